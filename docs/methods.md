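# Methods

## Data model

A `Table` is an ordered list of equal-length named `Column`s over text
cells, a per-row provenance label, and an optional `LocationSchema`. Three
choices define the model's behaviour:

- **Text cells, inferred types.** Cells are stored as the text read from
  the file (plus two special states: the `MISSING` singleton and the
  presence flag `True`). A column's type — `integer`, `real`, `flag` or
  `text` — is inferred (integer if every non-missing cell parses as an
  integer, real if every one parses as a real, flag if every one is a
  presence flag, otherwise text) and used only where an operation needs it
  (numeric predicates, score validation on export). Nothing is coerced, so
  `export → read` round trips are cell-identical and inference is
  idempotent. An all-missing column is text: there is no evidence for a
  narrower type.
- **One missing state.** `MISSING` is a singleton distinct from every
  concrete value including `""`. Both empty cells (when the missing symbol
  is empty) and a user-specified symbol such as `.` map to it on read; on
  export it renders as the caller's chosen symbol. Flags render as `1`.
- **Deterministic naming.** Auto-assigned names are `col_1 … col_n`;
  name collisions (notably after merges) resolve by appending the lowest
  free `_2`, `_3`, … suffix, first occurrence keeping the bare name. This
  is lossless and deterministic; nothing is silently overwritten.

Row identity is positional; row names are never required or maintained.
Capacity is limited only by memory.

## Coordinates

The canonical interval is 0-based half-open with optional strand
(BED-style). Rationale: overlap arithmetic stays closed under zero-length
intervals (insertion points), and most export targets use this convention.
Three schema encodings cover the demonstrated inputs: `three_column`
(chrom/start/end), `chrom_pos` (VCF-style; interval length is `len(REF)`
when a `REF` column exists, else 1), and `locus_string`
(`chr1:101-200`). The basis (`zero_half_open` or `one_closed`) is
mandatory — no schema without a declared convention; `one_closed` converts
by `start ← start − 1`.

The overlap predicate is true when both intervals share a chromosome
(exact string comparison; an opt-in flag strips `chr` prefixes) and the
overlap length is positive and at least `min_fraction × len(query)`. The
fraction is measured against the **left/query** interval only; reciprocal
overlap is out of scope. A zero-length query counts as overlapping when
its point lies in `[start, end)` of the other interval; a zero-length
*stored* interval never overlaps a positive-length query (overlap length
is 0). Strand is carried but only restricts matches when the
strand-matching flag is set.

The interval index keeps one interval tree per chromosome (the
`intervaltree` package) for candidate retrieval, padding zero-length
entries inside the tree only, and re-checks every candidate with the exact
predicate. Query results are therefore identical to an exhaustive scan by
construction, which the property tests assert against a brute-force
all-pairs oracle.

## Reading

`read_delimited` applies the dialect: comment and blank lines skipped,
quote-aware splitting only when a quote character is declared, cells equal
to the missing symbol become `MISSING`. Header policy `auto` takes the
first non-comment row as a header iff one of its cells fails numeric
parsing while the next row's cell at the same position succeeds; this
heuristic is deliberately simple and documented rather than clever — pass
`first_row`/`none` when the file is known. A data row whose field count
differs from the header is a structural error naming the line.

`read_vcf` parses the meta-header (`##` lines, declared INFO IDs, sample
ids from `#CHROM`) and keeps the seven fixed columns verbatim (`.` stays
`.`, since VCF's own missing marker is meaningful text there). INFO
expansion collects the union of keys over all records in first-appearance
order — declared or not — into `INFO.<KEY>` columns; value-less keys are
flags. Values stay raw text because undeclared keys carry no
`Number=`/`Type=` declaration to trust; numeric typing happens by
inference. Multi-allelic ALT stays one comma-joined cell: the engine
treats files as tabular text, not variant semantics. FORMAT/sample columns
are kept verbatim or dropped (`expand_samples`).

`read_track` skips `track`/`browser`/comment lines and dispatches to BED
(tab or whitespace split, 3–12 canonical columns), GFF/GTF (9 tab columns;
GTF attributes are not key-expanded), PSL (21 columns, optional header
block skipped) or WIG (fixedStep/variableStep blocks expanded to one
`(chrom, start, end, value)` row per value line, converting WIG's 1-based
starts and honouring `step` and `span`). Auto-detection inspects the first
data line and fails listing the formats tried. Gzip input is accepted by
`.gz` suffix.

## Merging

Location joins extract both tables' canonical intervals, index the right
side, and match per left row; `exact_interval` compares `(chrom, start,
end)` after conversion (strand is ignored, consistent with overlap
semantics where strand never restricts by default). Key joins compare 1–4
column pairs as whitespace-trimmed text; `MISSING` never matches anything,
including another `MISSING`, and numeric equivalence (`1` vs `1.0`) is
deliberately not applied. More than 4 key pairs is a specification error.

Output columns are left's followed by right's, collisions suffixed; rows
are ordered by ascending (left row, right row) index; `first_match` breaks
ties toward the lowest right index. Matched rows get provenance
`left+right`; unmatched `left_outer` rows keep the left label (no right
row exists to cite). Right- and full-outer joins are omitted — swap the
arguments for the right-outer effect.

`append` unions column names in first-appearance order, stacks same-named
columns and fills absent cells with `MISSING`; it is associative up to
cell identity, and preserves the common location schema when all inputs
share one.

## Filtering

Predicates: numeric comparisons require a numeric-typed column and parse
both sides as reals; text equality trims surrounding whitespace;
`contains` is a case-sensitive substring test. `on_missing` defaults to
`drop` — a row with missing data cannot certify a condition. Regular
expressions are deliberately not supported.

Criteria filtering pre-filters the criteria table with an optional
predicate (e.g. `score > 0.85`), indexes the surviving intervals, and
keeps or drops the data rows overlapping at least one of them at the
requested minimum fraction. The two polarities partition the input by
construction; raising `min_fraction` can only shrink the kept set.

Sample presence: the sample key is the tuple of 1–4 sample-column cells,
record identity defaults to all remaining columns. The denominator is the
number of distinct sample keys **observed in the table** (the data gives no
external roster); `total_samples` overrides it when a roster is known.
Rows whose sample key contains `MISSING` cannot be attributed and are
excluded from the roster, the counts and the output.

## Reduction and export

`select_columns` and `deduplicate` (first row of each key tuple wins) are
the reduction primitives; the location schema is dropped when its columns
are pruned. `export_tab` writes UTF-8, LF, tab-delimited, verbatim cells —
a cell containing a tab or newline is an error naming row and column, not
a silently quoted value.

Track export always derives coordinates from the canonical intervals and
re-emits them in the target's native convention, so cross-format
conversion is exact. Field layouts follow the UCSC/ENCODE definitions:
BED is written at the width implied by the highest bound optional field
(3–12), BED detail appends ID and description, BED6+3 is 9 fields,
narrowPeak 10 (unbound peak defaults to `-1`, "no point source"),
broadPeak 9, gappedPeak 15, peptideMapping 10, PSL 21, GFF 9
(version-2-style single `group` field), pgSnp 7 (unbound allele
count/frequency/score default to `1`/`0`/`0`). Unbound optional fields
take the UCSC defaults (name `.`, score `0`, strand `.`); scores outside
[0, 1000] are clamped with a warning rather than rejected, since browser
upload is the point of these files. WIG is read but not exported. A table
without a location schema cannot be exported to a coordinate format.

## Pipelines and CLI

The YAML pipeline validates exhaustively before reading any data (every
problem reported, not just the first), executes steps in order logging
`rows in → rows out` per step to standard error, and writes the output via
a temp-file-and-rename so a failed run never leaves a partial file. The
CLI is a thin layer over the same functions; exit codes are 0 (success),
2 (usage/validation), 1 (runtime). There is no randomness anywhere in the
engine, so identical inputs and config produce byte-identical outputs.

## Synthetic fixtures

The fixture generators produce the shapes the engine must handle, with
ground-truth sidecars so tests never derive expectations through the
parser under test: a VCF whose declared keys (`DP`, `AF`) appear in every
record while undeclared keys (`MYCALLER_SCORE`, a `NOVEL` flag) appear in
a random 40 % of records; score tracks where exactly
`round(n × fraction_conserved)` intervals score above the 0.85
conservation cutoff (defaults: 100 intervals, fraction 0.3, mirroring the
conservation-shortlisting workflow); and a cohort table with one row per
(locus, carrier sample). Defaults place 100 variants over three
chromosomes in a 100 kb coordinate space so variants and criteria tracks
generated from the same spec overlap at testable rates. Everything is
driven by `random.Random(seed)`; the same seed yields byte-identical
files.

What the fixtures do **not** emulate: linkage structure, allele-frequency
spectra, mutation signatures, realistic chromosome sizes, or malformed
real-world files beyond the dialect features the readers declare. Passing
tests therefore demonstrate correct mechanics (parsing, coordinate
arithmetic, join/filter semantics, format compliance), not robustness to
arbitrarily broken inputs.

## Verification sizes and numerical choices

The oracle comparisons run at sizes chosen to exercise the index and
grouping paths well past the trivial range while keeping the whole suite
fast: the join oracle at 500×500 intervals over three chromosomes
(≈ 250 000 candidate pairs), criteria partitioning on 20 seeded fixtures,
the sample-filter double loop at ≈ 1 700–2 000 rows across thresholds
{0.25, 0.5, 0.75, 1.0}, and the conservation scenario at 200 variants ×
100 intervals. All comparisons are exact (set or sequence equality, byte
equality for determinism); there are no floating-point tolerances anywhere
in the engine because no floating-point arithmetic is performed beyond
predicate comparisons on parsed values.

## Known limitations

No genotype/FORMAT semantics, no GFF3 attribute assembly, no record
splitting of multi-allelic sites, no liftover or chromosome aliasing, no
reciprocal-overlap or nearest-feature joins, no bigWig/bigBed or tabix,
and no enforcement of browser upload size limits. These are boundaries,
not omissions: the engine stops where tabular text ends and variant
semantics begin.
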