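"""Universal in-memory table model.

Every operation in genotab — merging, filtering, reduction, export — runs on
one container, :class:`Table`: an ordered list of equal-length named columns
of cells, with a per-row provenance label recording which source file each
row came from, and an optional :class:`~genotab.location.LocationSchema`
declaring how genomic coordinates are encoded.

Cells are deliberately *text*: a cell is a ``str``, the :data:`MISSING`
sentinel, or flag-``True`` (a presence flag, as produced by VCF INFO keys
without a value). Numeric typing is *inferred* per column and carried as
metadata; the underlying text is never coerced, which is what makes
read → export round trips cell-identical. MISSING is a singleton distinct
from every concrete value including the empty string, so both empty cells
and a user-specified missing symbol collapse to one internal state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

from .errors import SchemaError, StructuralError

if TYPE_CHECKING:  # pragma: no cover
    from .location import LocationSchema


class _Missing:
    """Singleton sentinel for a missing cell."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


MISSING = _Missing()

#: A cell: raw text, a presence flag, or missing.
Cell = "str | bool | _Missing"

_INT_RE = re.compile(r"[+-]?\d+\Z")


def as_cell(value) -> "str | bool | _Missing":
    """Normalize an arbitrary Python value into a cell."""
    if value is MISSING or value is None:
        return MISSING
    if value is True:
        return True
    if isinstance(value, bool):  # False flag: treated as absent
        return MISSING
    if isinstance(value, str):
        return value
    return str(value)


def cell_text(cell) -> str:
    """Render a cell as text; flags render as ``1``. MISSING is refused."""
    if cell is MISSING:
        raise ValueError("MISSING has no text form; supply a missing symbol")
    if cell is True:
        return "1"
    return cell


def is_missing(cell) -> bool:
    return cell is MISSING


def parse_int(text: str):
    """Return int(text) if text is a plain integer literal, else None."""
    s = text.strip()
    if _INT_RE.match(s):
        return int(s)
    return None


def parse_real(text: str):
    """Return float(text) if parseable as a real number, else None."""
    s = text.strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def infer_column_type(values: Iterable) -> str:
    """Infer one of ``text``, ``integer``, ``real``, ``flag`` for a column.

    Integer wins if every non-missing cell parses as an integer; real if
    every one parses as a real; flag if every non-missing cell is a presence
    flag; anything else (including an all-missing column) is text.
    """
    saw_value = False
    all_int = all_real = all_flag = True
    for v in values:
        if v is MISSING:
            continue
        saw_value = True
        if v is True:
            all_int = all_real = False
            continue
        all_flag = False
        if all_int and parse_int(v) is None:
            all_int = False
        if all_real and parse_real(v) is None:
            all_real = False
        if not (all_int or all_real):
            break
    if not saw_value:
        return "text"
    if all_flag:
        return "flag"
    if all_int:
        return "integer"
    if all_real:
        return "real"
    return "text"


@dataclass
class Column:
    """A named, ordered sequence of cells with an inferred type."""

    name: str
    values: list
    inferred_type: str = "text"

    @classmethod
    def build(cls, name: str, values: Iterable) -> "Column":
        vals = [as_cell(v) for v in values]
        return cls(name, vals, infer_column_type(vals))

    def __len__(self) -> int:
        return len(self.values)


def auto_name_columns(n: int) -> list[str]:
    """Deterministic automatic column names ``col_1`` ... ``col_n``."""
    return [f"col_{i}" for i in range(1, n + 1)]


def uniquify_names(names: Sequence[str]) -> list[str]:
    """Resolve duplicate names by appending ``_2``, ``_3``, ...

    The first occurrence keeps its name; later occurrences get the lowest
    suffix not already present in the output so far.
    """
    seen: set[str] = set()
    out: list[str] = []
    for name in names:
        if name not in seen:
            seen.add(name)
            out.append(name)
            continue
        k = 2
        while f"{name}_{k}" in seen:
            k += 1
        new = f"{name}_{k}"
        seen.add(new)
        out.append(new)
    return out


@dataclass
class Dialect:
    """Parsing parameters for one delimited input file."""

    delimiter: str = "\t"
    comment_char: str | None = "#"
    missing_symbol: str = ""
    header: str = "auto"  # first_row | none | auto
    quote_char: str | None = None

    def __post_init__(self):
        if len(self.delimiter) != 1:
            raise StructuralError(
                f"delimiter must be a single character, got {self.delimiter!r}"
            )
        if self.comment_char is not None and self.delimiter == self.comment_char:
            raise StructuralError(
                f"delimiter and comment character are both {self.delimiter!r}"
            )
        if self.header not in ("first_row", "none", "auto"):
            raise StructuralError(f"unknown header policy {self.header!r}")


class Table:
    """Ordered columns of cells + per-row provenance + optional location schema."""

    def __init__(
        self,
        columns: list[Column],
        provenance: list[str],
        location_schema: "LocationSchema | None" = None,
    ):
        n = len(columns[0]) if columns else len(provenance)
        for col in columns:
            if len(col) != n:
                raise StructuralError(
                    f"column {col.name!r} has {len(col)} cells, expected {n}"
                )
        if len(provenance) != n:
            raise StructuralError(
                f"provenance has {len(provenance)} entries for {n} rows"
            )
        names = [c.name for c in columns]
        if len(set(names)) != len(names):
            raise StructuralError(f"duplicate column names: {names}")
        self.columns = columns
        self.provenance = provenance
        self.location_schema = location_schema
        self._by_name = {c.name: c for c in columns}

    # -- basic introspection -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.provenance)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def has_column(self, name: str) -> bool:
        return name in self._by_name

    def column(self, name: str) -> Column:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"no column named {name!r}") from None

    def __getitem__(self, name: str) -> Column:
        return self.column(name)

    def row(self, i: int) -> list:
        return [c.values[i] for c in self.columns]

    def rows(self):
        for i in range(self.n_rows):
            yield self.row(i)

    def cell(self, row: int, name: str):
        return self.column(name).values[row]

    # -- derivation ----------------------------------------------------------
    def subset_rows(self, indices: Sequence[int]) -> "Table":
        """New Table with the given rows (in the given order), columns unchanged."""
        cols = [
            Column(c.name, [c.values[i] for i in indices], c.inferred_type)
            for c in self.columns
        ]
        prov = [self.provenance[i] for i in indices]
        return Table(cols, prov, self.location_schema)

    def copy(self) -> "Table":
        cols = [Column(c.name, list(c.values), c.inferred_type) for c in self.columns]
        return Table(cols, list(self.provenance), self.location_schema)

    def with_schema(self, schema: "LocationSchema | None") -> "Table":
        t = self.copy()
        t.location_schema = schema
        return t

    def __repr__(self) -> str:
        return f"<Table {self.n_rows}x{self.n_columns} {self.column_names}>"


def make_table(
    column_names: Sequence[str],
    rows: Sequence[Sequence],
    source_label: str,
    location_schema: "LocationSchema | None" = None,
) -> Table:
    """Build a Table from a row grid, inferring column types.

    Column-name collisions are resolved with numeric suffixes; provenance is
    filled with ``source_label`` for every row. Ragged rows are a structural
    error naming the offending row index.
    """
    ncol = len(column_names)
    for i, r in enumerate(rows):
        if len(r) != ncol:
            raise StructuralError(
                f"row {i} has {len(r)} cells, expected {ncol}"
            )
    names = uniquify_names(list(column_names))
    cols = [
        Column.build(names[j], (r[j] for r in rows)) for j in range(ncol)
    ]
    return Table(cols, [source_label] * len(rows), location_schema)
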