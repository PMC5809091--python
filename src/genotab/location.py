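"""Genomic coordinate conventions and interval arithmetic.

Genomic file formats disagree on how an interval is written: BED is 0-based
half-open, GFF/GTF and VCF positions are 1-based closed, and free-form tab
files may carry a single ``chr1:101-200`` locus string. This module
normalizes them all to one canonical representation — :class:`Interval`,
0-based half-open, BED-style — which keeps overlap arithmetic closed under
zero-length intervals (insertion points) and matches most export targets.

A :class:`LocationSchema` attached to a table declares which columns encode
coordinates and in which convention, so interval operations (overlap joins,
criteria filtering) work on *any* table, not just ones read from a
coordinate-bearing format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .core import MISSING, Table, cell_text, parse_int
from .errors import DataError, SchemaError

ZERO_HALF_OPEN = "zero_half_open"
ONE_CLOSED = "one_closed"


@dataclass(frozen=True)
class Interval:
    """Canonical genomic interval: 0-based half-open, optional strand.

    ``end >= start``; ``end == start`` denotes a zero-length insertion point.
    Chromosome names are plain text and compared exactly (no ``chr`` prefix
    normalization unless a caller asks for it).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise DataError("interval with empty chromosome name")
        if self.start < 0:
            raise DataError(f"negative interval start: {self.start}")
        if self.end < self.start:
            raise DataError(f"interval end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class LocationSchema:
    """Declares where a table's genomic coordinates live and their basis.

    encoding:
        ``three_column`` — (chrom, start, end) columns;
        ``chrom_pos`` — (chrom, pos) columns, interval length taken from a
        ``REF`` column when one exists (VCF-derived tables), else 1;
        ``locus_string`` — one column holding ``chrom:start-end`` text.
    basis:
        ``zero_half_open`` (BED) or ``one_closed`` (GFF/VCF); mandatory.
    """

    encoding: str
    column_names: tuple
    basis: str
    strand_column: str | None = None

    def __post_init__(self):
        expected = {"three_column": 3, "chrom_pos": 2, "locus_string": 1}
        if self.encoding not in expected:
            raise SchemaError(f"unknown location encoding {self.encoding!r}")
        if len(self.column_names) != expected[self.encoding]:
            raise SchemaError(
                f"{self.encoding} needs {expected[self.encoding]} column "
                f"name(s), got {self.column_names!r}"
            )
        if self.basis not in (ZERO_HALF_OPEN, ONE_CLOSED):
            raise SchemaError(f"unknown coordinate basis {self.basis!r}")


def _parse_coord(cell, what: str, row: int) -> int:
    if cell is MISSING:
        raise DataError(f"row {row}: missing {what} coordinate")
    v = parse_int(cell_text(cell))
    if v is None:
        raise DataError(f"row {row}: cannot parse {what} coordinate {cell!r}")
    return v


def _to_canonical(start: int, end: int, basis: str, row: int) -> tuple:
    if basis == ONE_CLOSED:
        start -= 1
    if start < 0:
        raise DataError(f"row {row}: negative start after basis conversion")
    if end < start:
        raise DataError(f"row {row}: end {end} < start {start}")
    return start, end


def extract_intervals(table: Table) -> list[Interval]:
    """One canonical Interval per table row, following the table's schema."""
    schema = table.location_schema
    if schema is None:
        raise SchemaError("table has no location schema")
    strand_col = (
        table.column(schema.strand_column) if schema.strand_column else None
    )
    out: list[Interval] = []
    if schema.encoding == "three_column":
        c_chrom = table.column(schema.column_names[0])
        c_start = table.column(schema.column_names[1])
        c_end = table.column(schema.column_names[2])
        for i in range(table.n_rows):
            chrom = _chrom_text(c_chrom.values[i], i)
            start = _parse_coord(c_start.values[i], "start", i)
            end = _parse_coord(c_end.values[i], "end", i)
            start, end = _to_canonical(start, end, schema.basis, i)
            out.append(Interval(chrom, start, end, _strand(strand_col, i)))
    elif schema.encoding == "chrom_pos":
        c_chrom = table.column(schema.column_names[0])
        c_pos = table.column(schema.column_names[1])
        ref = table.column("REF") if table.has_column("REF") else None
        for i in range(table.n_rows):
            chrom = _chrom_text(c_chrom.values[i], i)
            pos = _parse_coord(c_pos.values[i], "position", i)
            length = 1
            if ref is not None and ref.values[i] is not MISSING:
                length = max(1, len(cell_text(ref.values[i])))
            start = pos - 1 if schema.basis == ONE_CLOSED else pos
            if start < 0:
                raise DataError(f"row {i}: negative start after basis conversion")
            out.append(
                Interval(chrom, start, start + length, _strand(strand_col, i))
            )
    else:  # locus_string
        c_locus = table.column(schema.column_names[0])
        for i in range(table.n_rows):
            cell = c_locus.values[i]
            if cell is MISSING:
                raise DataError(f"row {i}: missing locus string")
            chrom, start, end = _parse_locus(cell_text(cell), i)
            start, end = _to_canonical(start, end, schema.basis, i)
            out.append(Interval(chrom, start, end, _strand(strand_col, i)))
    return out


def _chrom_text(cell, row: int) -> str:
    if cell is MISSING:
        raise DataError(f"row {row}: missing chromosome")
    return cell_text(cell).strip()


def _strand(col, i: int) -> str:
    if col is None:
        return "."
    v = col.values[i]
    if v is MISSING:
        return "."
    s = cell_text(v).strip()
    return s if s in ("+", "-") else "."


def _parse_locus(text: str, row: int) -> tuple:
    s = text.strip()
    if ":" not in s or "-" not in s.split(":", 1)[1]:
        raise DataError(f"row {row}: cannot parse locus string {text!r}")
    chrom, rest = s.split(":", 1)
    a, b = rest.split("-", 1)
    start, end = parse_int(a), parse_int(b)
    if not chrom or start is None or end is None:
        raise DataError(f"row {row}: cannot parse locus string {text!r}")
    return chrom, start, end


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix for prefix-insensitive comparison."""
    return name[3:] if name.startswith("chr") else name


def overlaps(
    a: Interval,
    b: Interval,
    min_fraction: float = 0.0,
    *,
    normalize: bool = False,
    match_strand: bool = False,
) -> bool:
    """True iff ``a`` and ``b`` overlap by at least ``min_fraction`` of ``a``.

    ``min_fraction`` is measured against the left/query interval only.
    Zero means any positive overlap. A zero-length ``a`` counts as
    overlapping iff its point lies in ``[b.start, b.end)``.
    """
    a_chrom = normalize_chrom(a.chrom) if normalize else a.chrom
    b_chrom = normalize_chrom(b.chrom) if normalize else b.chrom
    if a_chrom != b_chrom:
        return False
    if match_strand and a.strand != b.strand:
        return False
    if len(a) == 0:
        return b.start <= a.start < b.end
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov >= min_fraction * len(a)


class IntervalIndex:
    """Overlap index over a fixed interval sequence.

    Backed by one interval tree per chromosome for candidate retrieval;
    every candidate is re-checked with the exact :func:`overlaps` predicate,
    so query results are identical to an exhaustive scan. Zero-length
    intervals are padded inside the tree only.
    """

    def __init__(self, intervals: Sequence[Interval], *, normalize: bool = False):
        self.intervals = list(intervals)
        self.normalize = normalize
        self._trees: dict[str, IntervalTree] = {}
        for idx, iv in enumerate(self.intervals):
            chrom = normalize_chrom(iv.chrom) if normalize else iv.chrom
            tree = self._trees.setdefault(chrom, IntervalTree())
            tree.addi(iv.start, max(iv.end, iv.start + 1), idx)

    def query(
        self,
        interval: Interval,
        min_fraction: float = 0.0,
        *,
        match_strand: bool = False,
    ) -> list[int]:
        """Indices of stored intervals overlapping ``interval``, ascending."""
        chrom = (
            normalize_chrom(interval.chrom) if self.normalize else interval.chrom
        )
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        lo, hi = interval.start, max(interval.end, interval.start + 1)
        hits = []
        for node in tree.overlap(lo, hi):
            idx = node.data
            if overlaps(
                interval,
                self.intervals[idx],
                min_fraction,
                normalize=self.normalize,
                match_strand=match_strand,
            ):
                hits.append(idx)
        hits.sort()
        return hits

    def __len__(self) -> int:
        return len(self.intervals)


def build_interval_index(
    intervals: Sequence[Interval], *, normalize: bool = False
) -> IntervalIndex:
    """Construct an :class:`IntervalIndex` (overlap queries ≡ exhaustive scan)."""
    return IntervalIndex(intervals, normalize=normalize)
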