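"""Convert a VCF to a BED custom track.

Builds a small synthetic VCF (with an undeclared INFO key, as real callers
emit), reads it with full INFO expansion, and exports a BED file whose
coordinates are shifted from the VCF's 1-based positions to BED's 0-based
half-open convention automatically.
"""

import tempfile
from pathlib import Path

from genotab import ColumnMapping, export_track, read_vcf
from genotab.fixtures import FixtureSpec, make_vcf_fixture

with tempfile.TemporaryDirectory() as tmp:
    vcf_path = Path(tmp) / "calls.vcf"
    make_vcf_fixture(FixtureSpec(seed=11, n_variants=5, n_samples=0),
                     vcf_path)

    table, meta = read_vcf(vcf_path)
    print(f"read {table.n_rows} variants, columns: {table.column_names}")
    print(f"INFO keys declared in the header: {sorted(meta.declared_info_keys)}")

    bed_path = Path(tmp) / "calls.bed"
    export_track(table, ColumnMapping("bed", {"name": "ID"}), bed_path,
                 track_line='track name="variants"')
    print("\nBED output (0-based starts = VCF POS - 1):")
    print(bed_path.read_text())
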