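"""Deterministic synthetic input generator.

Produces the small genomic files the test-suite and examples run on — a VCF
with declared *and* undeclared INFO keys, score-bearing criteria tracks
(BED/GFF/WIG) with a controlled fraction of high-conservation intervals,
and a multi-sample variant table with known per-locus sample presence.

Every generator writes a machine-readable ground-truth sidecar
(``<file>.truth.json``) next to the fixture, so tests never have to derive
expectations through the parser under test. The same seed always yields
byte-identical files.

These fixtures emulate the *shape* of real data (coordinate conventions,
INFO layout, score tracks), not its biology: positions are uniform, alleles
are random bases, and scores are uniform draws, so they exercise parsing,
joining and filtering logic rather than any biological signal.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling fixture generation.

    ``position_space`` bounds 1-based positions/starts so variant and
    criteria fixtures built from the same spec land in overlapping
    coordinate ranges. ``fraction_conserved`` is the exact fraction of
    criteria intervals given a score above the 0.85 conservation cutoff.
    """

    seed: int = 0
    n_variants: int = 100
    n_samples: int = 3
    n_criteria_intervals: int = 100
    chroms: tuple = ("chr1", "chr2", "chr3")
    declared_info_keys: tuple = ("DP", "AF")
    extra_info_keys: tuple = ("MYCALLER_SCORE", "NOVEL")
    fraction_conserved: float = 0.3
    position_space: int = 100_000


def _truth_path(path) -> str:
    return os.fspath(path) + ".truth.json"


def _write_truth(path, truth) -> None:
    with open(_truth_path(path), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_truth(path):
    """Read the ground-truth sidecar written next to a fixture file."""
    with open(_truth_path(path), encoding="utf-8") as fh:
        return json.load(fh)


def make_vcf_fixture(spec: FixtureSpec, path) -> dict:
    """Write a VCF fixture; return its ground truth (also saved as sidecar).

    ``##INFO`` declarations cover only ``declared_info_keys``; the
    ``extra_info_keys`` appear in record INFO fields undeclared —
    ``NOVEL``-style keys as value-less flags, others as ``key=value``.
    Ground truth lists each record's fields and fully expanded INFO map.
    """
    rng = random.Random(spec.seed)
    records = []
    for i in range(spec.n_variants):
        chrom = rng.choice(spec.chroms)
        pos = rng.randrange(1, spec.position_space + 1)
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        info: dict = {}
        for key in spec.declared_info_keys:
            if key == "AF":
                info[key] = f"{rng.uniform(0.0, 1.0):.3f}"
            else:
                info[key] = str(rng.randrange(1, 200))
        for key in spec.extra_info_keys:
            if rng.random() < 0.4:
                if key == "NOVEL":
                    info[key] = True
                else:
                    info[key] = f"{rng.uniform(0.0, 1.0):.3f}"
        records.append(
            {"CHROM": chrom, "POS": pos, "ID": f"var{i + 1}", "REF": ref,
             "ALT": alt, "QUAL": str(rng.randrange(10, 100)),
             "FILTER": "PASS", "INFO": info}
        )
    records.sort(key=lambda r: (r["CHROM"], r["POS"]))

    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    lines = ["##fileformat=VCFv4.2"]
    for key in spec.declared_info_keys:
        num, typ = ("1", "Float") if key == "AF" else ("1", "Integer")
        lines.append(
            f'##INFO=<ID={key},Number={num},Type={typ},Description="{key}">'
        )
    if samples:
        lines.append(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
        )
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header += ["FORMAT"] + samples
    lines.append("\t".join(header))
    genotypes = []
    for rec in records:
        info_txt = ";".join(
            k if v is True else f"{k}={v}" for k, v in rec["INFO"].items()
        ) or "."
        row = [rec["CHROM"], str(rec["POS"]), rec["ID"], rec["REF"],
               rec["ALT"], rec["QUAL"], rec["FILTER"], info_txt]
        if samples:
            gts = [rng.choice(["0/0", "0/1", "1/1"]) for _ in samples]
            genotypes.append(gts)
            row += ["GT"] + gts
        lines.append("\t".join(row))
    with open(os.fspath(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")

    truth = {
        "records": [
            {**{k: rec[k] for k in
                ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER")},
             "info": {k: (True if v is True else v)
                      for k, v in rec["INFO"].items()}}
            for rec in records
        ],
        "sample_ids": samples,
        "declared_info_keys": sorted(spec.declared_info_keys),
        "all_info_keys": sorted(
            {k for rec in records for k in rec["INFO"]}
        ),
    }
    _write_truth(path, truth)
    return truth


def _criteria_intervals(spec: FixtureSpec):
    """Canonical (chrom, start, end, score, conserved) tuples, deterministic."""
    rng = random.Random(spec.seed + 1)
    n = spec.n_criteria_intervals
    n_conserved = round(n * spec.fraction_conserved)
    conserved_flags = [i < n_conserved for i in range(n)]
    rng.shuffle(conserved_flags)
    out = []
    for i in range(n):
        chrom = rng.choice(spec.chroms)
        start = rng.randrange(0, max(1, spec.position_space - 500))
        length = rng.randrange(50, 400)
        if conserved_flags[i]:
            score = round(rng.uniform(0.851, 1.0), 3)
        else:
            score = round(rng.uniform(0.0, 0.849), 3)
        out.append((chrom, start, start + length, score, conserved_flags[i]))
    return out


def make_track_fixture(spec: FixtureSpec, fmt: str, path) -> dict:
    """Write a score-bearing criteria track (bed, gff or wig) + ground truth.

    Exactly ``round(n * fraction_conserved)`` intervals carry a score above
    0.85 (the conservation cutoff used when the track stands in for a
    phastCons conservation track). Ground truth lists every interval in
    canonical 0-based half-open coordinates with its score. For WIG the
    intervals are re-laid as fixedStep blocks (one per chromosome) whose
    expansion yields exactly ``n`` rows.
    """
    if fmt not in ("bed", "gff", "wig"):
        raise ValueError(f"unsupported track fixture format {fmt!r}")
    intervals = _criteria_intervals(spec)
    lines = []
    if fmt == "bed":
        for i, (chrom, start, end, score, _) in enumerate(intervals):
            lines.append(f"{chrom}\t{start}\t{end}\tiv{i + 1}\t{score}")
        score_column = "score"
    elif fmt == "gff":
        for chrom, start, end, score, _ in intervals:
            lines.append(
                f"{chrom}\tfixture\tregion\t{start + 1}\t{end}\t{score}"
                f"\t+\t.\t."
            )
        score_column = "score"
    else:  # wig: contiguous fixedStep blocks, span/step fixed per block
        span, step = 200, 300
        by_chrom: dict = {}
        relaid = []
        for (chrom, _s, _e, score, cons) in intervals:
            by_chrom.setdefault(chrom, []).append((score, cons))
        for chrom in sorted(by_chrom):
            start1 = 101
            lines.append(
                f"fixedStep chrom={chrom} start={start1} step={step} "
                f"span={span}"
            )
            for k, (score, cons) in enumerate(by_chrom[chrom]):
                lines.append(str(score))
                s0 = start1 - 1 + k * step
                relaid.append((chrom, s0, s0 + span, score, cons))
        intervals = relaid
        score_column = "value"
    with open(os.fspath(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    truth = {
        "format": fmt,
        "score_column": score_column,
        "intervals": [
            {"chrom": c, "start": s, "end": e, "score": score,
             "conserved": cons}
            for c, s, e, score, cons in intervals
        ],
        "n_conserved": sum(1 for *_x, cons in intervals if cons),
    }
    _write_truth(path, truth)
    return truth


def make_multisample_fixture(spec: FixtureSpec, path) -> dict:
    """Write a (locus, sample, genotype) tab file + per-locus presence truth.

    Each locus appears in a random non-empty subset of the samples; the
    ground truth records, per locus, the set of carrying samples and the
    presence fraction over samples observed anywhere in the table.
    """
    rng = random.Random(spec.seed + 2)
    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    rows = []
    presence: dict = {}
    n_loci = max(1, spec.n_variants)
    for i in range(n_loci):
        while True:  # loci must be unique for the ground truth to be a map
            chrom = rng.choice(spec.chroms)
            pos = rng.randrange(1, spec.position_space + 1)
            locus = f"{chrom}:{pos}"
            if locus not in presence:
                break
        k = rng.randrange(1, spec.n_samples + 1)
        carriers = sorted(rng.sample(samples, k))
        presence[locus] = carriers
        for s in carriers:
            rows.append((locus, s, rng.choice(["0/1", "1/1"])))
    observed = sorted({s for carriers in presence.values() for s in carriers})
    lines = ["locus\tsample\tgenotype"]
    lines += [f"{l}\t{s}\t{g}" for l, s, g in rows]
    with open(os.fspath(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    truth = {
        "samples": samples,
        "observed_samples": observed,
        "loci": {
            locus: {
                "carriers": carriers,
                "presence": len(carriers) / len(observed),
            }
            for locus, carriers in presence.items()
        },
        "n_rows": len(rows),
    }
    _write_truth(path, truth)
    return truth
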