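"""Reduce a rich annotation table and export a browser-ready custom track.

Probe-level aCGH output carries long oligo sequences and properties that a
genome browser neither needs nor accepts. Selecting the coordinate and
score columns and exporting as BED gives a small, valid custom track.
"""

import tempfile
from pathlib import Path

from genotab import (
    ColumnMapping,
    LocationSchema,
    export_tab,
    export_track,
    make_table,
    select_columns,
)

rows = [["chr1", "agilent", "probe", i * 120 + 1, i * 120 + 60,
         f"{(i % 5) * 0.4 - 1:.2f}", "+", ".",
         f"probe=A_14_P{100000 + i};seq={'ACGT' * 15}"]
        for i in range(20)]
acgh = make_table(
    ["seqname", "source", "feature", "start", "end", "score", "strand",
     "frame", "attribute"],
    rows, "acgh.gff",
    LocationSchema("three_column", ("seqname", "start", "end"), "one_closed"))

with tempfile.TemporaryDirectory() as tmp:
    full, small = Path(tmp) / "full.tsv", Path(tmp) / "small.tsv"
    export_tab(acgh, full)
    reduced = select_columns(acgh, ["seqname", "start", "end", "score"])
    export_tab(reduced, small)
    print(f"full export: {full.stat().st_size} bytes; "
          f"reduced: {small.stat().st_size} bytes "
          f"({small.stat().st_size / full.stat().st_size:.0%} of full)")

    track = Path(tmp) / "ratios.bed"
    export_track(acgh, ColumnMapping("bed", {"name": "feature"}), track,
                 track_line='track name="log2 ratios"')
    print("\nfirst BED lines (GFF 1-based starts became 0-based):")
    print("\n".join(track.read_text().splitlines()[:4]))
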