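# genotab

Merging, filtering, reducing and converting character-delimited genomic
data tables — VCF, BED, GFF/GTF, PSL, WIG and arbitrary tab/CSV files —
as a scriptable Python library with a thin command-line front end.

## The problem

High-throughput genomics produces stacks of tabular text files that almost,
but not quite, share a format: variant callers emit VCFs whose INFO fields
carry undeclared, caller-specific keys; annotation services return
tab-delimited lists that drop the caller's technical fields; array and
sequencing results live in GFF and custom tab files; and genome browsers
demand strictly formatted BED/ENCODE tracks with a different coordinate
convention than the inputs. The day-to-day analysis work — join the raw
calls back onto the annotated list, keep only variants inside accessible
regions, select those at positions conserved above a phastCons score of
0.85, slim the columns, export a custom track — is glue work between
formats, and genotab is that glue as a composable engine.

## The model

Everything operates on one container, the `Table`: ordered, equal-length,
named columns of *text* cells, plus a `MISSING` sentinel (distinct from the
empty string; both empty cells and a user-chosen missing symbol map to it),
a per-row provenance label recording the source file, and an optional
`LocationSchema` declaring which columns encode genomic coordinates and in
which convention. Column types (`integer`, `real`, `flag`, `text`) are
inferred, never coerced, so reading and re-exporting a file is
cell-identical.

Coordinates are normalized internally to 0-based half-open intervals
(BED-style). A GFF row `(chr1, 101, 200)` in its native 1-based closed
convention and a BED row `(chr1, 100, 200)` denote the same interval
[100, 200); a VCF record at `POS = p` with reference allele REF covers
[p−1, p−1+|REF|). Overlap joins and criteria filters run on an interval
index whose query results are provably identical to an exhaustive scan,
with the overlap fraction measured against the left/query interval.

Capabilities, each a small set of pure functions:

- **readers** — any delimited dialect (delimiter, comment char, missing
  symbol, header policy, quoting, gzip); VCF with every observed INFO key
  expanded to an `INFO.<KEY>` column whether declared or not; BED, GFF/GTF,
  PSL and WIG (fixedStep/variableStep expanded to intervals).
- **merge** — horizontal by genomic location (overlap with a minimum
  fraction, or exact interval) or by 1–4 key columns compared as trimmed
  text; inner or left-outer; one row per matching pair or first match only.
  Vertical append by column-name union.
- **filters** — column predicates, external value lists, criteria tracks
  (optionally pre-filtered by a score predicate, keeping or dropping
  overlapping rows), and sample-presence percentage over 1–4
  sample-identifying columns.
- **reduce/export** — column selection, deduplication, tab-delimited
  output, and UCSC/ENCODE track formats: BED, BED detail, PSL, GFF,
  Personal Genome SNP, BED6+3, narrowPeak, broadPeak, gappedPeak,
  peptideMapping — coordinates re-emitted in each format's native
  convention.
- **pipeline/CLI** — `genotab convert|merge|append|filter|samples|reduce`,
  and `genotab pipeline config.yaml` for itemized, reusable condition sets
  with exhaustive up-front validation and per-step row-count logging.
- **fixtures** — deterministic synthetic VCF/track/cohort generators with
  ground-truth sidecars, used throughout the tests and examples.

## Worked example

`examples/03_filter_by_conservation_track.py` generates 100 synthetic
variants and a 60-interval conservation track (30 % of intervals scored
above 0.85), then keeps the variants overlapping a conserved interval:

```
100 variants; 60 track intervals, of which those with score > 0.85 act as criteria
kept (overlap a conserved interval):   3
dropped (no conserved overlap):        97
kept + dropped == input: True
```

The two polarities (`keep_overlapping` / `drop_overlapping`) always
partition the input exactly — 3 + 97 = 100 — and the 3 kept variants are
those whose position falls inside one of the high-score intervals. The
other scripts in `examples/` cover conversion, key-column merging,
sample-presence filtering, data reduction and YAML pipelines; each prints
the numbers it computes and what they mean.

The same workflow from the shell:

```sh
genotab filter calls.vcf conserved.tsv \
    --criteria conservation.bed --criteria-where score:gt:0.85
```

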