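"""Horizontal and vertical table merging.

Two horizontal axes: by genomic location (overlap or exact-interval match
between the canonical intervals of two located tables) and by equality of
1-4 key column pairs, compared as trimmed text. Vertical merging appends
tables by column-name union, stacking same-named columns and filling
absent cells with MISSING.

Join multiplicity: ``expand_pairs`` emits one output row per matching
(left, right) pair; ``first_match`` keeps at most one per left row, tied
to the lowest right row index. Right-outer joins are not offered — swap
the arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .core import MISSING, Column, Table, cell_text, infer_column_type, uniquify_names
from .errors import SchemaError, SpecificationError
from .location import build_interval_index, extract_intervals

MAX_KEY_COLUMNS = 4


@dataclass
class JoinSpec:
    """How two tables are joined.

    mode: ``inner`` drops left rows with no match; ``left_outer`` keeps them
    with right-hand cells MISSING.
    predicate: ``overlap`` (with ``min_fraction`` of the left interval),
    ``exact_interval``, or ``key_equality`` on ``key_columns``
    (1-4 (left, right) column-name pairs).
    """

    mode: str = "inner"
    predicate: str = "overlap"
    min_fraction: float = 0.0
    key_columns: list = dc_field(default_factory=list)
    multiplicity: str = "expand_pairs"

    def __post_init__(self):
        if self.mode not in ("inner", "left_outer"):
            raise SpecificationError(f"unknown join mode {self.mode!r}")
        if self.predicate not in ("overlap", "exact_interval", "key_equality"):
            raise SpecificationError(f"unknown predicate {self.predicate!r}")
        if self.multiplicity not in ("expand_pairs", "first_match"):
            raise SpecificationError(
                f"unknown multiplicity {self.multiplicity!r}"
            )
        if not 0.0 <= self.min_fraction <= 1.0:
            raise SpecificationError("min_fraction must be in [0, 1]")


def _merged_provenance(left: Table, right: Table, pairs) -> list[str]:
    prov = []
    for li, ri in pairs:
        if ri is None:
            prov.append(left.provenance[li])
        else:
            prov.append(f"{left.provenance[li]}+{right.provenance[ri]}")
    return prov


def _assemble(left: Table, right: Table, pairs) -> Table:
    """Build the joined table from (left_index, right_index-or-None) pairs."""
    names = uniquify_names(left.column_names + right.column_names)
    cols: list[Column] = []
    for j, col in enumerate(left.columns):
        vals = [col.values[li] for li, _ in pairs]
        cols.append(Column(names[j], vals, infer_column_type(vals)))
    off = left.n_columns
    for j, col in enumerate(right.columns):
        vals = [
            MISSING if ri is None else col.values[ri] for _, ri in pairs
        ]
        cols.append(Column(names[off + j], vals, infer_column_type(vals)))
    return Table(cols, _merged_provenance(left, right, pairs),
                 left.location_schema)


def _select_pairs(matches_per_left, spec: JoinSpec):
    """Apply mode and multiplicity to per-left-row match lists."""
    pairs = []
    for li, matches in enumerate(matches_per_left):
        if matches:
            if spec.multiplicity == "first_match":
                pairs.append((li, matches[0]))
            else:
                pairs.extend((li, ri) for ri in matches)
        elif spec.mode == "left_outer":
            pairs.append((li, None))
    return pairs


def merge_by_location(left: Table, right: Table, spec: JoinSpec) -> Table:
    """Join two located tables on interval overlap or exact interval identity.

    Output columns are left's followed by right's (collisions suffixed);
    rows are ordered by ascending (left row, right row) index.
    """
    if spec.predicate not in ("overlap", "exact_interval"):
        raise SpecificationError(
            "merge_by_location needs an overlap or exact_interval predicate"
        )
    if left.location_schema is None:
        raise SchemaError("left table has no location schema")
    if right.location_schema is None:
        raise SchemaError("right table has no location schema")
    left_iv = extract_intervals(left)
    right_iv = extract_intervals(right)

    matches_per_left: list[list[int]] = []
    if spec.predicate == "exact_interval":
        by_key: dict[tuple, list[int]] = {}
        for ri, iv in enumerate(right_iv):
            by_key.setdefault(iv.key(), []).append(ri)
        for iv in left_iv:
            matches_per_left.append(by_key.get(iv.key(), []))
    else:
        index = build_interval_index(right_iv)
        for iv in left_iv:
            matches_per_left.append(index.query(iv, spec.min_fraction))
    return _assemble(left, right, _select_pairs(matches_per_left, spec))


def _key_tuple(table: Table, row: int, columns) -> tuple | None:
    """Trimmed-text key tuple for a row; None if any key cell is MISSING."""
    out = []
    for name in columns:
        cell = table.cell(row, name)
        if cell is MISSING:
            return None
        out.append(cell_text(cell).strip())
    return tuple(out)


def merge_by_keys(left: Table, right: Table, spec: JoinSpec) -> Table:
    """Join on equality of 1-4 key column pairs, compared as trimmed text.

    MISSING never matches anything, including another MISSING. Numeric
    equivalence (``1`` vs ``1.0``) is deliberately NOT applied: text files
    are compared as text.
    """
    if spec.predicate != "key_equality":
        raise SpecificationError("merge_by_keys needs a key_equality predicate")
    if not 1 <= len(spec.key_columns) <= MAX_KEY_COLUMNS:
        raise SpecificationError(
            f"key_equality joins take 1 to {MAX_KEY_COLUMNS} key column "
            f"pairs (max 4), got {len(spec.key_columns)}"
        )
    left_keys = [pair[0] for pair in spec.key_columns]
    right_keys = [pair[1] for pair in spec.key_columns]
    for name in left_keys:
        left.column(name)  # raises SchemaError naming the column
    for name in right_keys:
        right.column(name)

    by_key: dict[tuple, list[int]] = {}
    for ri in range(right.n_rows):
        key = _key_tuple(right, ri, right_keys)
        if key is not None:
            by_key.setdefault(key, []).append(ri)

    matches_per_left = []
    for li in range(left.n_rows):
        key = _key_tuple(left, li, left_keys)
        matches_per_left.append([] if key is None else by_key.get(key, []))
    return _assemble(left, right, _select_pairs(matches_per_left, spec))


def append(tables: list[Table]) -> Table:
    """Stack tables vertically by column-name union.

    Output columns are the union of input column names in first-appearance
    order; a cell absent from a source table is MISSING. Row provenance is
    preserved. A single table returns a cell-identical copy.
    """
    if not tables:
        raise SpecificationError("append needs at least one table")
    names: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for name in t.column_names:
            if name not in seen:
                seen.add(name)
                names.append(name)
    values: dict[str, list] = {name: [] for name in names}
    prov: list[str] = []
    for t in tables:
        n = t.n_rows
        prov.extend(t.provenance)
        present = set(t.column_names)
        for name in names:
            if name in present:
                values[name].extend(t.column(name).values)
            else:
                values[name].extend([MISSING] * n)
    cols = [
        Column(name, values[name], infer_column_type(values[name]))
        for name in names
    ]
    schema = tables[0].location_schema if len(tables) == 1 else None
    for t in tables:
        if t.location_schema is not None and all(
            t.location_schema == u.location_schema for u in tables
        ):
            schema = t.location_schema
        break
    return Table(cols, prov, schema)
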