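import random

import pytest

from genotab.core import MISSING
from genotab.location import Interval


def write(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)


@pytest.fixture
def writefile(tmp_path):
    """Write text to a file under tmp_path and return its path."""

    def _write(name, text):
        p = tmp_path / name
        p.write_text(text, encoding="utf-8")
        return str(p)

    return _write


def random_intervals(rng: random.Random, n, chroms=("chr1", "chr2", "chr3"),
                     space=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = rng.randrange(0, space)
        out.append(
            Interval(rng.choice(chroms), start,
                     start + rng.randrange(1, max_len))
        )
    return out


def tables_equal(a, b) -> bool:
    """Cell-identical comparison of two Tables (names, cells, provenance)."""
    if a.column_names != b.column_names or a.n_rows != b.n_rows:
        return False
    for ca, cb in zip(a.columns, b.columns):
        for x, y in zip(ca.values, cb.values):
            if (x is MISSING) != (y is MISSING):
                return False
            if x is not MISSING and x != y:
                return False
    return True
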