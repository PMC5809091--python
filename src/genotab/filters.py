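"""Row filtering: column predicates, value lists, criteria tracks, samples.

Four filter families, all row-subset operations (output rows are a
subsequence of input rows; columns never change):

* :func:`filter_rows` — per-column predicates (eq/ne/lt/le/gt/ge/contains/
  in_list) combined with all/any, e.g. keeping variants with a phastCons
  conservation score above 0.85.
* :func:`filter_by_list` — membership of a cell in an external one-value-
  per-line list (e.g. a gene shortlist), optionally negated.
* :func:`filter_by_criteria` — overlap against an external criteria track
  (BED/GFF/WIG/...), optionally pre-filtered by a score predicate, keeping
  or dropping the overlapping rows. This is the accessible-regions /
  conservation-track workflow.
* :func:`filter_by_sample_presence` — keeps records present in a given
  fraction of samples, where 1-4 columns identify the sample and the
  remaining columns define record identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .core import MISSING, Table, cell_text, parse_real
from .errors import (
    ColumnTypeError,
    DataError,
    SchemaError,
    SpecificationError,
)
from .location import build_interval_index, extract_intervals

_NUMERIC_OPS = {"lt", "le", "gt", "ge"}
_ALL_OPS = _NUMERIC_OPS | {"eq", "ne", "contains", "in_list"}


@dataclass
class Predicate:
    """One condition on one column.

    Numeric operators (lt/le/gt/ge) require a numeric-typed column and
    compare cell and operand as reals. eq/ne compare trimmed text;
    ``contains`` is a case-sensitive substring test; ``in_list`` tests
    membership in a text list. ``on_missing`` decides whether a MISSING
    cell satisfies the predicate (``keep``) or fails it (``drop``, the
    default: a row with missing data cannot certify a condition).
    """

    column: str
    op: str
    operand: object
    on_missing: str = "drop"

    def __post_init__(self):
        if self.op not in _ALL_OPS:
            raise SpecificationError(f"unknown predicate operator {self.op!r}")
        if self.on_missing not in ("drop", "keep"):
            raise SpecificationError(
                f"on_missing must be drop or keep, got {self.on_missing!r}"
            )
        if self.op == "in_list":
            values = list(self.operand)
            if not values:
                raise SpecificationError("in_list operand must be non-empty")
            self.operand = [str(v) for v in values]


def _eval_predicate(pred: Predicate, table: Table, row: int) -> bool:
    col = table.column(pred.column)
    cell = col.values[row]
    if cell is MISSING:
        return pred.on_missing == "keep"
    if pred.op in _NUMERIC_OPS:
        if col.inferred_type not in ("integer", "real"):
            raise ColumnTypeError(
                f"numeric predicate {pred.op!r} on text column {pred.column!r}"
            )
        x = parse_real(cell_text(cell))
        y = parse_real(str(pred.operand))
        if y is None:
            raise SpecificationError(
                f"operand {pred.operand!r} is not numeric"
            )
        return {
            "lt": x < y, "le": x <= y, "gt": x > y, "ge": x >= y,
        }[pred.op]
    text = cell_text(cell).strip()
    if pred.op == "eq":
        return text == str(pred.operand).strip()
    if pred.op == "ne":
        return text != str(pred.operand).strip()
    if pred.op == "contains":
        return str(pred.operand) in cell_text(cell)
    return text in pred.operand  # in_list


def filter_rows(
    table: Table, predicates: list, combine: str = "all"
) -> Table:
    """Keep rows satisfying the combined predicates; order preserved.

    An empty predicate list with ``combine='all'`` keeps every row
    (vacuous truth); with ``'any'`` it keeps none.
    """
    if combine not in ("all", "any"):
        raise SpecificationError(f"combine must be all or any, got {combine!r}")
    for p in predicates:
        table.column(p.column)
    agg = all if combine == "all" else any
    keep = [
        i for i in range(table.n_rows)
        if agg(_eval_predicate(p, table, i) for p in predicates)
    ]
    return table.subset_rows(keep)


def read_value_list(path_or_stream) -> list[str]:
    """Values from a one-value-per-line file; blanks and # comments ignored."""
    from .readers import _open_text  # local import avoids a cycle

    values = []
    with _open_text(path_or_stream) as stream:
        for raw in stream:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            values.append(line)
    return values


def filter_by_list(
    table: Table, column: str, list_path, negate: bool = False
) -> Table:
    """Keep rows whose trimmed cell text is in (or not in) an external list.

    MISSING never matches, so under ``negate`` MISSING rows are kept (they
    are not in the list). An effectively empty list is a specification
    error — almost certainly a user mistake.
    """
    values = set(read_value_list(list_path))
    if not values:
        raise SpecificationError(
            f"value list {list_path!r} is empty after removing comments"
        )
    col = table.column(column)
    keep = []
    for i in range(table.n_rows):
        cell = col.values[i]
        member = cell is not MISSING and cell_text(cell).strip() in values
        if member != negate:
            keep.append(i)
    return table.subset_rows(keep)


@dataclass
class CriteriaSpec:
    """An external criteria track and how to apply it.

    ``criteria_predicate`` (optional) pre-filters criteria rows before
    indexing — e.g. keep only conservation intervals with score > 0.85.
    ``polarity`` keeps or drops the data rows overlapping any surviving
    criteria interval; ``min_fraction`` is the overlap fraction demanded of
    the data row's interval.
    """

    criteria_table: Table
    polarity: str = "keep_overlapping"
    min_fraction: float = 0.0
    criteria_predicate: Predicate | None = None

    def __post_init__(self):
        if self.polarity not in ("keep_overlapping", "drop_overlapping"):
            raise SpecificationError(f"unknown polarity {self.polarity!r}")
        if not 0.0 <= self.min_fraction <= 1.0:
            raise SpecificationError("min_fraction must be in [0, 1]")


def filter_by_criteria(table: Table, spec: CriteriaSpec) -> Table:
    """Keep or drop data rows overlapping an external criteria track."""
    if table.location_schema is None:
        raise SchemaError("data table has no location schema")
    criteria = spec.criteria_table
    if criteria.location_schema is None:
        raise SchemaError("criteria table has no location schema")
    if spec.criteria_predicate is not None:
        criteria = filter_rows(criteria, [spec.criteria_predicate])
    index = build_interval_index(extract_intervals(criteria))
    want_overlap = spec.polarity == "keep_overlapping"
    keep = []
    for i, iv in enumerate(extract_intervals(table)):
        hit = bool(index.query(iv, spec.min_fraction))
        if hit == want_overlap:
            keep.append(i)
    return table.subset_rows(keep)


@dataclass
class SampleSpec:
    """Sample-presence filtering parameters.

    ``sample_columns`` (1-4) identify the sample a row belongs to;
    ``identity_columns`` define record identity (default: all non-sample
    columns). A record identity is kept when the fraction of distinct
    observed samples it appears in is >= (``at_least``) or <= (``at_most``)
    ``threshold``. ``total_samples`` optionally overrides the observed
    sample count with an external roster size.
    """

    sample_columns: list
    identity_columns: list | None = None
    threshold: float = 0.5
    direction: str = "at_least"
    total_samples: int | None = None

    def __post_init__(self):
        if not 1 <= len(self.sample_columns) <= 4:
            raise SpecificationError(
                "sample_columns takes 1 to 4 column names"
            )
        if not 0.0 < self.threshold <= 1.0:
            raise SpecificationError("threshold must be in (0, 1]")
        if self.direction not in ("at_least", "at_most"):
            raise SpecificationError(
                f"direction must be at_least or at_most, got "
                f"{self.direction!r}"
            )
        if self.identity_columns is not None:
            overlap = set(self.sample_columns) & set(self.identity_columns)
            if overlap:
                raise SpecificationError(
                    f"sample and identity columns overlap: {sorted(overlap)}"
                )


def _tuple_of(table: Table, row: int, columns) -> tuple | None:
    vals = []
    for name in columns:
        cell = table.cell(row, name)
        if cell is MISSING:
            return None
        vals.append(cell_text(cell))
    return tuple(vals)


def filter_by_sample_presence(table: Table, spec: SampleSpec) -> Table:
    """Keep rows of record identities present in enough (or few enough) samples.

    The sample roster defaults to the distinct sample-key tuples observed in
    the table itself. Rows whose sample key contains MISSING cannot be
    attributed to a sample and are excluded from the roster and the
    presence counts (they are dropped from the output).
    """
    for name in spec.sample_columns:
        table.column(name)
    identity_cols = spec.identity_columns
    if identity_cols is None:
        identity_cols = [
            n for n in table.column_names if n not in spec.sample_columns
        ]
    else:
        for name in identity_cols:
            table.column(name)

    samples_of: dict[tuple, set] = {}
    observed: set = set()
    row_identity: list = []
    for i in range(table.n_rows):
        skey = _tuple_of(table, i, spec.sample_columns)
        ikey = _tuple_of(table, i, identity_cols)
        row_identity.append((ikey, skey))
        if skey is None or ikey is None:
            continue
        observed.add(skey)
        samples_of.setdefault(ikey, set()).add(skey)

    total = spec.total_samples if spec.total_samples is not None else len(observed)
    if total <= 0:
        raise DataError("no attributable samples in the table")

    keep = []
    for i, (ikey, skey) in enumerate(row_identity):
        if ikey is None or skey is None:
            continue
        presence = len(samples_of[ikey]) / total
        ok = (
            presence >= spec.threshold
            if spec.direction == "at_least"
            else presence <= spec.threshold
        )
        if ok:
            keep.append(i)
    return table.subset_rows(keep)
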