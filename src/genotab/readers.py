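"""Parsers turning delimited genomic files into Tables.

Handles arbitrary character-delimited text (user-chosen delimiter, comment
character, missing symbol, header policy), VCF with meta-headers and
non-canonical INFO entries, and the UCSC track formats BED, GFF/GTF, PSL and
WIG. Every reader returns a :class:`~genotab.core.Table`; coordinate-bearing
formats attach the matching :class:`~genotab.location.LocationSchema` so the
result is immediately usable in location joins and criteria filters.

VCF INFO handling is the deliberate centrepiece: every key observed in any
record — whether or not a ``##INFO`` meta line declares it — becomes an
``INFO.<KEY>`` column. Value-less keys are presence flags; values are kept
as raw text (numeric typing happens by inference downstream), because
undeclared keys carry no Number=/Type= declaration to trust.
"""

from __future__ import annotations

import csv
import gzip
import io
import os
from contextlib import contextmanager
from dataclasses import dataclass, field

from .core import (
    MISSING,
    Column,
    Dialect,
    Table,
    auto_name_columns,
    parse_real,
    uniquify_names,
)
from .errors import FormatError, ReadError, StructuralError
from .location import ONE_CLOSED, ZERO_HALF_OPEN, LocationSchema

BED_FIELD_NAMES = [
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
    "blockStarts",
]

GFF_FIELD_NAMES = [
    "seqname", "source", "feature", "start", "end", "score", "strand",
    "frame", "attribute",
]

PSL_FIELD_NAMES = [
    "matches", "misMatches", "repMatches", "nCount", "qNumInsert",
    "qBaseInsert", "tNumInsert", "tBaseInsert", "strand", "qName", "qSize",
    "qStart", "qEnd", "tName", "tSize", "tStart", "tEnd", "blockCount",
    "blockSizes", "qStarts", "tStarts",
]

BED_SCHEMA = LocationSchema(
    "three_column", ("chrom", "chromStart", "chromEnd"), ZERO_HALF_OPEN,
    strand_column="strand",
)
GFF_SCHEMA = LocationSchema(
    "three_column", ("seqname", "start", "end"), ONE_CLOSED,
    strand_column="strand",
)
PSL_SCHEMA = LocationSchema(
    "three_column", ("tName", "tStart", "tEnd"), ZERO_HALF_OPEN,
    strand_column="strand",
)
WIG_SCHEMA = LocationSchema(
    "three_column", ("chrom", "start", "end"), ZERO_HALF_OPEN
)
VCF_SCHEMA = LocationSchema("chrom_pos", ("CHROM", "POS"), ONE_CLOSED)


@contextmanager
def _open_text(path_or_stream):
    """Yield a text stream for a path (gzip by ``.gz`` suffix) or file-like."""
    if hasattr(path_or_stream, "read"):
        yield path_or_stream
        return
    path = os.fspath(path_or_stream)
    try:
        if path.endswith(".gz"):
            fh = gzip.open(path, "rt", encoding="utf-8")
        else:
            fh = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise ReadError(f"cannot read {path!r}: {exc}") from exc
    try:
        yield fh
    finally:
        fh.close()


def _source_label(path_or_stream) -> str:
    if hasattr(path_or_stream, "read"):
        return getattr(path_or_stream, "name", "<stream>")
    return os.path.basename(os.fspath(path_or_stream))


def _numbered_lines(stream):
    for lineno, raw in enumerate(stream, start=1):
        yield lineno, raw.rstrip("\n").rstrip("\r")


def read_delimited(path_or_stream, dialect: Dialect | None = None) -> Table:
    """Parse any character-delimited file into a Table.

    Comment lines (prefix = ``comment_char``) and blank lines are skipped.
    Header policy ``auto`` takes the first non-comment row as a header iff
    any of its cells fails numeric parsing while the next row's cell at the
    same position succeeds; otherwise columns are auto-named. Cells equal to
    the dialect's missing symbol become MISSING.
    """
    dialect = dialect or Dialect()
    label = _source_label(path_or_stream)
    with _open_text(path_or_stream) as stream:
        kept: list[tuple[int, str]] = []
        for lineno, line in _numbered_lines(stream):
            if not line:
                continue
            if dialect.comment_char and line.startswith(dialect.comment_char):
                continue
            kept.append((lineno, line))

    rows: list[tuple[int, list[str]]] = []
    if dialect.quote_char:
        reader = csv.reader(
            (line for _, line in kept),
            delimiter=dialect.delimiter,
            quotechar=dialect.quote_char,
        )
        for (lineno, _), fields in zip(kept, reader):
            rows.append((lineno, fields))
    else:
        for lineno, line in kept:
            rows.append((lineno, line.split(dialect.delimiter)))

    if not rows:
        return Table([], [], None)

    header_mode = dialect.header
    if header_mode == "auto":
        header_mode = "first_row" if _looks_like_header(rows) else "none"

    if header_mode == "first_row":
        names = uniquify_names([f.strip() for f in rows[0][1]])
        data = rows[1:]
    else:
        names = auto_name_columns(len(rows[0][1]))
        data = rows

    ncol = len(names)
    columns = [[] for _ in range(ncol)]
    for lineno, fields in data:
        if len(fields) != ncol:
            raise StructuralError(
                f"{label}: line {lineno} has {len(fields)} fields, "
                f"expected {ncol}"
            )
        for j, cell in enumerate(fields):
            columns[j].append(
                MISSING if cell == dialect.missing_symbol else cell
            )
    cols = [Column.build(names[j], columns[j]) for j in range(ncol)]
    return Table(cols, [label] * len(data))


def _looks_like_header(rows) -> bool:
    if len(rows) < 2:
        return False
    first, second = rows[0][1], rows[1][1]
    for j in range(min(len(first), len(second))):
        if parse_real(first[j]) is None and parse_real(second[j]) is not None:
            return True
    return False


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_FIXED = ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER"]


@dataclass
class VcfMeta:
    """VCF meta-header content: ``##`` lines, sample ids, declared INFO keys."""

    meta_lines: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)
    declared_info_keys: set = field(default_factory=set)


def _parse_info(info: str):
    """Split an INFO field into an ordered key → value-or-flag mapping."""
    result: dict[str, object] = {}
    if info in (".", ""):
        return result
    for entry in info.split(";"):
        if not entry:
            continue
        if "=" in entry:
            key, value = entry.split("=", 1)
            result[key] = value
        else:
            result[entry] = True
    return result


def read_vcf(
    path_or_stream,
    expand_info: bool = True,
    expand_samples: bool = True,
) -> tuple[Table, VcfMeta]:
    """Parse a VCF into a Table plus its meta-header description.

    Fixed columns CHROM..FILTER are retained verbatim. With ``expand_info``,
    every key observed in any record's INFO — declared or not — becomes an
    ``INFO.<KEY>`` column: flag keys get flag-true where present and MISSING
    elsewhere; ``key=value`` entries keep the raw value text. With
    ``expand_samples``, FORMAT and one column per sample are kept verbatim.
    The result carries the VCF location convention (1-based positions,
    interval length from REF).
    """
    label = _source_label(path_or_stream)
    meta = VcfMeta()
    header_fields = None
    records: list[tuple[int, list[str]]] = []
    with _open_text(path_or_stream) as stream:
        for lineno, line in _numbered_lines(stream):
            if not line:
                continue
            if line.startswith("##"):
                meta.meta_lines.append(line)
                if line.startswith("##INFO=<"):
                    body = line[len("##INFO=<"):].rstrip(">")
                    for part in body.split(","):
                        if part.startswith("ID="):
                            meta.declared_info_keys.add(part[3:])
                            break
                continue
            if line.startswith("#"):
                header_fields = line[1:].split("\t")
                continue
            if header_fields is None:
                raise FormatError(f"{label}: no #CHROM header line before data")
            fields = line.split("\t")
            if len(fields) < 8:
                raise StructuralError(
                    f"{label}: line {lineno} has {len(fields)} fields, "
                    "VCF requires at least 8"
                )
            records.append((lineno, fields))
    if header_fields is None:
        raise FormatError(f"{label}: no #CHROM header line found")
    if header_fields[0] != "CHROM":
        raise FormatError(
            f"{label}: header line must begin with #CHROM, got "
            f"#{header_fields[0]}"
        )
    meta.sample_ids = header_fields[9:] if len(header_fields) > 9 else []

    n = len(records)
    cols: list[Column] = [
        Column.build(name, [rec[i] for _, rec in records])
        for i, name in enumerate(VCF_FIXED)
    ]

    if expand_info:
        parsed = [_parse_info(rec[7]) for _, rec in records]
        info_keys: list[str] = []
        seen: set[str] = set()
        for p in parsed:
            for k in p:
                if k not in seen:
                    seen.add(k)
                    info_keys.append(k)
        for key in info_keys:
            cols.append(
                Column.build(
                    f"INFO.{key}", [p.get(key, MISSING) for p in parsed]
                )
            )
    else:
        cols.append(Column.build("INFO", [rec[7] for _, rec in records]))

    if expand_samples and len(header_fields) > 8:
        for i, name in enumerate(header_fields[8:], start=8):
            cols.append(
                Column.build(
                    name,
                    [rec[i] if len(rec) > i else MISSING for _, rec in records],
                )
            )

    names = uniquify_names([c.name for c in cols])
    for c, nm in zip(cols, names):
        c.name = nm
    table = Table(cols, [label] * n, VCF_SCHEMA)
    return table, meta


# ---------------------------------------------------------------------------
# UCSC track formats
# ---------------------------------------------------------------------------

def _track_lines(stream):
    """Data lines of a UCSC track file; ``track``/``browser``/# lines skipped."""
    for lineno, line in _numbered_lines(stream):
        if not line.strip():
            continue
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        if stripped.startswith("track ") or stripped == "track":
            continue
        if stripped.startswith("browser ") or stripped == "browser":
            continue
        yield lineno, line


def _read_bed(lines, label: str) -> Table:
    rows = []
    ncol = None
    for lineno, line in lines:
        fields = line.split("\t") if "\t" in line else line.split()
        if not 3 <= len(fields) <= 12:
            raise FormatError(
                f"{label}: line {lineno} has {len(fields)} fields; "
                "BED requires 3-12"
            )
        if ncol is None:
            ncol = len(fields)
        elif len(fields) != ncol:
            raise StructuralError(
                f"{label}: line {lineno} has {len(fields)} fields, "
                f"expected {ncol}"
            )
        rows.append(fields)
    ncol = ncol or 3
    names = BED_FIELD_NAMES[:ncol]
    cols = [Column.build(names[j], [r[j] for r in rows]) for j in range(ncol)]
    schema = BED_SCHEMA if ncol >= 6 else LocationSchema(
        "three_column", ("chrom", "chromStart", "chromEnd"), ZERO_HALF_OPEN
    )
    return Table(cols, [label] * len(rows), schema)


def _read_gff(lines, label: str) -> Table:
    rows = []
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(
                f"{label}: line {lineno} has {len(fields)} fields; "
                "GFF/GTF requires 9"
            )
        rows.append(fields)
    cols = [
        Column.build(GFF_FIELD_NAMES[j], [r[j] for r in rows])
        for j in range(9)
    ]
    return Table(cols, [label] * len(rows), GFF_SCHEMA)


_PSL_HEADER_STARTS = ("psLayout", "match", "-")


def _read_psl(lines, label: str) -> Table:
    rows = []
    for lineno, line in lines:
        first = line.split("\t")[0].split(" ")[0]
        if any(line.startswith(h) for h in _PSL_HEADER_STARTS) and not (
            first.lstrip("-").isdigit() and first
        ):
            continue  # optional 5-line header block
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 21:
            raise FormatError(
                f"{label}: line {lineno} has {len(fields)} fields; "
                "PSL requires 21"
            )
        rows.append(fields)
    cols = [
        Column.build(PSL_FIELD_NAMES[j], [r[j] for r in rows])
        for j in range(21)
    ]
    return Table(cols, [label] * len(rows), PSL_SCHEMA)


def _parse_wig_declaration(line: str) -> dict:
    parts = line.split()
    decl = {"kind": parts[0]}
    for part in parts[1:]:
        if "=" in part:
            k, v = part.split("=", 1)
            decl[k] = v
    return decl


def _read_wig(lines, label: str) -> Table:
    """Expand fixedStep/variableStep blocks to (chrom, start, end, value) rows.

    WIG starts are 1-based; output rows are canonical 0-based half-open with
    ``end = start + span``.
    """
    rows = []
    decl = None
    next_start = None
    for lineno, line in lines:
        stripped = line.strip()
        if stripped.startswith(("fixedStep", "variableStep")):
            decl = _parse_wig_declaration(stripped)
            if "chrom" not in decl:
                raise FormatError(
                    f"{label}: line {lineno}: WIG declaration missing chrom="
                )
            if decl["kind"] == "fixedStep":
                if "start" not in decl:
                    raise FormatError(
                        f"{label}: line {lineno}: fixedStep missing start="
                    )
                next_start = int(decl["start"])
            continue
        if decl is None:
            raise StructuralError(
                f"{label}: line {lineno}: WIG data line outside any "
                "fixedStep/variableStep declaration"
            )
        span = int(decl.get("span", 1))
        if decl["kind"] == "fixedStep":
            start0 = next_start - 1
            rows.append((decl["chrom"], start0, start0 + span, stripped))
            next_start += int(decl.get("step", 1))
        else:
            parts = stripped.split()
            if len(parts) != 2:
                raise StructuralError(
                    f"{label}: line {lineno}: variableStep line needs "
                    "'position value'"
                )
            start0 = int(parts[0]) - 1
            rows.append((decl["chrom"], start0, start0 + span, parts[1]))
    cols = [
        Column.build("chrom", [r[0] for r in rows]),
        Column.build("start", [str(r[1]) for r in rows]),
        Column.build("end", [str(r[2]) for r in rows]),
        Column.build("value", [r[3] for r in rows]),
    ]
    return Table(cols, [label] * len(rows), WIG_SCHEMA)


_TRACK_READERS = {
    "bed": _read_bed,
    "gff": _read_gff,
    "gtf": _read_gff,  # same 9-column shape; attributes not expanded
    "psl": _read_psl,
    "wig": _read_wig,
}


def _detect_track_format(lines) -> str:
    for _, line in lines:
        if line.strip().startswith(("fixedStep", "variableStep")):
            return "wig"
        fields = line.split("\t") if "\t" in line else line.split()
        if line.startswith("psLayout") or len(fields) == 21:
            return "psl"
        if len(fields) == 9 and _is_int(fields[3]) and _is_int(fields[4]):
            return "gff"
        if 3 <= len(fields) <= 12 and _is_int(fields[1]) and _is_int(fields[2]):
            return "bed"
        break
    raise FormatError(
        "cannot auto-detect track format (tried wig, psl, gff, bed)"
    )


def _is_int(s: str) -> bool:
    return s.lstrip("+-").isdigit() and bool(s.lstrip("+-"))


def read_track(path_or_stream, format_hint: str = "auto") -> Table:
    """Parse a UCSC track file (BED, GFF/GTF, PSL or WIG) into a Table.

    ``track``/``browser`` declaration lines are skipped. Each format sets
    its native location schema on the result (BED/PSL/WIG canonical 0-based
    half-open, GFF/GTF 1-based closed).
    """
    label = _source_label(path_or_stream)
    with _open_text(path_or_stream) as stream:
        lines = list(_track_lines(stream))
    fmt = format_hint
    if fmt == "auto":
        fmt = _detect_track_format(lines)
    try:
        reader = _TRACK_READERS[fmt]
    except KeyError:
        raise FormatError(f"unknown track format {format_hint!r}") from None
    return reader(iter(lines), label)


def open_many(paths, dialects=None) -> list[Table]:
    """Open several delimited files, one Table per file, provenance = basename.

    ``dialects`` may be a per-path list or None (delimiter guessed from the
    extension: ``.csv`` → comma, anything else → tab). No combining happens
    here; that is the merge module's job.
    """
    paths = list(paths)
    if not paths:
        raise ReadError("no input files")
    if dialects is None:
        dialects = [None] * len(paths)
    if len(dialects) != len(paths):
        raise ReadError("one dialect per path required")
    tables = []
    for path, dialect in zip(paths, dialects):
        if dialect is None:
            base = os.fspath(path)
            delim = "," if base.endswith((".csv", ".csv.gz")) else "\t"
            dialect = Dialect(delimiter=delim)
        tables.append(read_delimited(path, dialect))
    return tables


def read_string(text: str, dialect: Dialect | None = None) -> Table:
    """Convenience: parse delimited content from a string."""
    return read_delimited(io.StringIO(text), dialect)
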