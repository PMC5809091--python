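"""Config-driven pipelines: itemized conditions from an external YAML file.

A pipeline config names its inputs (path + format + dialect, each bound to
an alias), an ordered list of steps (merge / append / filter / list /
criteria / samples / select / dedupe) that read and define aliases, and one
output (table alias + path + format + column mapping).

Validation is fail-fast and exhaustive: the whole config is checked —
unknown operations, undefined aliases, missing input files, malformed step
bodies — and *all* problems are reported before any data is read. Execution
logs per-step row counts (rows in → rows out) to a logger and writes the
final export atomically (temp file + rename), so a failing run never leaves
a partial output file.

Example config::

    inputs:
      - alias: variants
        path: calls.vcf
        format: vcf
      - alias: conservation
        path: cons.bed
        format: bed
    steps:
      - op: criteria
        table: variants
        criteria: conservation
        predicate: {column: score, op: gt, value: 0.85}
        polarity: keep_overlapping
        result: conserved
    output:
      table: conserved
      path: conserved.tsv
      format: tab
"""

from __future__ import annotations

import logging
import os
import tempfile

import yaml

from .core import Dialect, Table
from .errors import GenotabError, SpecificationError
from .filters import (
    CriteriaSpec,
    Predicate,
    SampleSpec,
    filter_by_criteria,
    filter_by_list,
    filter_by_sample_presence,
    filter_rows,
)
from .merge import JoinSpec, append, merge_by_keys, merge_by_location
from .readers import read_delimited, read_track, read_vcf
from .reduce_export import (
    ColumnMapping,
    Constant,
    deduplicate,
    export_tab,
    export_track,
    select_columns,
)

log = logging.getLogger("genotab.pipeline")

_INPUT_FORMATS = {"delimited", "vcf", "bed", "gff", "gtf", "psl", "wig", "track"}
_STEP_OPS = {
    "merge", "append", "filter", "list", "criteria", "samples", "select",
    "dedupe",
}
_OUTPUT_FORMATS = {
    "tab", "bed", "bed_detail", "bed6plus3", "narrowpeak", "broadpeak",
    "gappedpeak", "peptide_mapping", "personal_genome_snp", "gff", "psl",
}


class ConfigError(SpecificationError):
    """Raised with the full list of configuration problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def _dialect_from(d: dict | None) -> Dialect:
    d = d or {}
    return Dialect(
        delimiter=d.get("delimiter", "\t"),
        comment_char=d.get("comment", "#"),
        missing_symbol=d.get("missing", ""),
        header=d.get("header", "auto"),
        quote_char=d.get("quote"),
    )


def _predicate_from(d: dict) -> Predicate:
    return Predicate(
        column=d["column"],
        op=d["op"],
        operand=d.get("value", d.get("values")),
        on_missing=d.get("on_missing", "drop"),
    )


def load_config(path) -> dict:
    with open(os.fspath(path), encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(["config must be a YAML mapping"])
    return cfg


def validate_config(cfg: dict, base_dir: str = ".") -> list:
    """Return ALL problems found in the config (empty list = valid)."""
    problems = []
    aliases: set = set()
    inputs = cfg.get("inputs")
    if not isinstance(inputs, list) or not inputs:
        problems.append("config needs a non-empty 'inputs' list")
        inputs = []
    for i, inp in enumerate(inputs):
        where = f"inputs[{i}]"
        if not isinstance(inp, dict):
            problems.append(f"{where}: must be a mapping")
            continue
        alias = inp.get("alias")
        if not alias:
            problems.append(f"{where}: missing alias")
        elif alias in aliases:
            problems.append(f"{where}: duplicate alias {alias!r}")
        else:
            aliases.add(alias)
        path = inp.get("path")
        if not path:
            problems.append(f"{where}: missing path")
        elif not os.path.exists(os.path.join(base_dir, path)):
            problems.append(f"{where}: input file not found: {path}")
        fmt = inp.get("format", "delimited")
        if fmt not in _INPUT_FORMATS:
            problems.append(f"{where}: unknown input format {fmt!r}")

    steps = cfg.get("steps", [])
    if steps is None:
        steps = []
    if not isinstance(steps, list):
        problems.append("'steps' must be a list")
        steps = []
    for i, step in enumerate(steps):
        where = f"steps[{i}]"
        if not isinstance(step, dict):
            problems.append(f"{where}: must be a mapping")
            continue
        op = step.get("op")
        if op not in _STEP_OPS:
            problems.append(f"{where}: unknown op {op!r}")
            continue
        refs = []
        if op == "merge":
            refs = [step.get("left"), step.get("right")]
            if step.get("by", "location") not in ("location", "keys"):
                problems.append(f"{where}: merge 'by' must be location|keys")
        elif op == "append":
            tables = step.get("tables")
            if not isinstance(tables, list) or not tables:
                problems.append(f"{where}: append needs a 'tables' list")
                tables = []
            refs = list(tables)
        else:
            refs = [step.get("table")]
            if op == "criteria":
                refs.append(step.get("criteria"))
        for ref in refs:
            if ref is None:
                problems.append(f"{where}: missing a table reference")
            elif ref not in aliases:
                problems.append(
                    f"{where}: reference to undefined alias {ref!r}"
                )
        if op == "list":
            lp = step.get("path")
            if not lp:
                problems.append(f"{where}: list step needs 'path'")
            elif not os.path.exists(os.path.join(base_dir, lp)):
                problems.append(f"{where}: list file not found: {lp}")
        result = step.get("result", step.get("table") or step.get("left"))
        if result:
            aliases.add(result)

    out = cfg.get("output")
    if not isinstance(out, dict):
        problems.append("config needs an 'output' mapping")
    else:
        if not out.get("path"):
            problems.append("output: missing path")
        fmt = out.get("format", "tab")
        if fmt not in _OUTPUT_FORMATS:
            problems.append(f"output: unknown format {fmt!r}")
        ref = out.get("table")
        if not ref:
            problems.append("output: missing table alias")
        elif ref not in aliases:
            problems.append(f"output: reference to undefined alias {ref!r}")
    return problems


def _read_input(inp: dict, base_dir: str) -> Table:
    path = os.path.join(base_dir, inp["path"])
    fmt = inp.get("format", "delimited")
    if fmt == "vcf":
        table, _meta = read_vcf(
            path,
            expand_info=inp.get("expand_info", True),
            expand_samples=inp.get("expand_samples", True),
        )
        return table
    if fmt in ("bed", "gff", "gtf", "psl", "wig"):
        return read_track(path, fmt)
    if fmt == "track":
        return read_track(path, "auto")
    return read_delimited(path, _dialect_from(inp.get("dialect")))


def _run_step(step: dict, tables: dict, base_dir: str) -> tuple:
    """Execute one step; return (result_alias, result_table, n_in)."""
    op = step["op"]
    if op == "merge":
        left, right = tables[step["left"]], tables[step["right"]]
        n_in = left.n_rows
        by = step.get("by", "location")
        if by == "keys":
            pairs = [
                (str(k), str(v))
                for k, v in (p.split("=", 1) for p in step["keys"])
            ] if isinstance(step.get("keys"), list) else [
                tuple(p) for p in step.get("keys", [])
            ]
            spec = JoinSpec(
                mode=step.get("mode", "inner"),
                predicate="key_equality",
                key_columns=pairs,
                multiplicity=step.get("multiplicity", "expand_pairs"),
            )
            result = merge_by_keys(left, right, spec)
        else:
            spec = JoinSpec(
                mode=step.get("mode", "inner"),
                predicate=step.get("predicate", "overlap"),
                min_fraction=float(step.get("min_fraction", 0.0)),
                multiplicity=step.get("multiplicity", "expand_pairs"),
            )
            result = merge_by_location(left, right, spec)
        alias = step.get("result", step["left"])
    elif op == "append":
        parts = [tables[a] for a in step["tables"]]
        n_in = sum(t.n_rows for t in parts)
        result = append(parts)
        alias = step.get("result", step["tables"][0])
    else:
        table = tables[step["table"]]
        n_in = table.n_rows
        if op == "filter":
            preds = [_predicate_from(p) for p in step.get("predicates", [])]
            result = filter_rows(table, preds, step.get("combine", "all"))
        elif op == "list":
            result = filter_by_list(
                table, step["column"],
                os.path.join(base_dir, step["path"]),
                negate=bool(step.get("negate", False)),
            )
        elif op == "criteria":
            pred = step.get("predicate")
            spec = CriteriaSpec(
                criteria_table=tables[step["criteria"]],
                polarity=step.get("polarity", "keep_overlapping"),
                min_fraction=float(step.get("min_fraction", 0.0)),
                criteria_predicate=(
                    _predicate_from(pred) if pred else None
                ),
            )
            result = filter_by_criteria(table, spec)
        elif op == "samples":
            spec = SampleSpec(
                sample_columns=list(step["sample_columns"]),
                identity_columns=step.get("identity_columns"),
                threshold=float(step.get("threshold", 0.5)),
                direction=step.get("direction", "at_least"),
                total_samples=step.get("total_samples"),
            )
            result = filter_by_sample_presence(table, spec)
        elif op == "select":
            result = select_columns(table, list(step["columns"]))
        else:  # dedupe
            result = deduplicate(table, step.get("keys"))
        alias = step.get("result", step["table"])
    return alias, result, n_in


def _mapping_from(out: dict) -> ColumnMapping:
    fmt = out.get("format", "tab")
    bindings = {}
    for field_name, target in (out.get("mapping") or {}).items():
        if isinstance(target, str) and target.startswith("const:"):
            bindings[field_name] = Constant(target[len("const:"):])
        else:
            bindings[field_name] = str(target)
    return ColumnMapping(fmt, bindings)


def _export(table: Table, out: dict, base_dir: str) -> str:
    path = os.path.join(base_dir, out["path"])
    fmt = out.get("format", "tab")
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    os.close(fd)
    try:
        if fmt == "tab":
            export_tab(
                table, tmp,
                write_header=bool(out.get("header", True)),
                missing_symbol=str(out.get("missing", ".")),
            )
        else:
            export_track(
                table, _mapping_from(out), tmp,
                track_line=out.get("track_line"),
            )
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def run_pipeline(config_path) -> str:
    """Validate and execute a pipeline config; return the output path.

    Raises :class:`ConfigError` (listing every problem) before any data is
    read if the config is invalid; raises the underlying
    :class:`~genotab.errors.GenotabError` naming the failing step on a
    runtime failure.
    """
    config_path = os.fspath(config_path)
    base_dir = os.path.dirname(os.path.abspath(config_path))
    cfg = load_config(config_path)
    problems = validate_config(cfg, base_dir)
    if problems:
        raise ConfigError(problems)

    tables: dict = {}
    for inp in cfg["inputs"]:
        table = _read_input(inp, base_dir)
        tables[inp["alias"]] = table
        log.info("input %-16s %6d rows  (%s)", inp["alias"], table.n_rows,
                 inp["path"])
    for i, step in enumerate(cfg.get("steps") or []):
        try:
            alias, result, n_in = _run_step(step, tables, base_dir)
        except GenotabError as exc:
            raise type(exc)(f"step {i + 1} ({step.get('op')}): {exc}") from exc
        tables[alias] = result
        log.info("step %d %-10s %6d rows in -> %6d rows out  [%s]",
                 i + 1, step["op"], n_in, result.n_rows, alias)
    out = cfg["output"]
    path = _export(tables[out["table"]], out, base_dir)
    log.info("wrote %s (%d rows)", path, tables[out["table"]].n_rows)
    return path
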