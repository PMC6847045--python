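import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pdcovar.alignments import ColumnLabel, ConcatenatedAlignment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_alignment(protein_rows: list[str], site_rows: list[str] | None = None):
    """Build a ConcatenatedAlignment from raw row strings (test helper)."""
    n = len(protein_rows)
    plen = len(protein_rows[0]) if protein_rows else 0
    site_rows = site_rows or [""] * n
    slen = len(site_rows[0])
    columns = [ColumnLabel("protein", i + 1) for i in range(plen)] + [
        ColumnLabel("nucleotide", p)
        for p in [x for x in range(-(slen // 2), slen - slen // 2 + 1) if x != 0][:slen]
    ]
    matrix = np.array(
        [list(p) + list(s) for p, s in zip(protein_rows, site_rows)], dtype="<U1"
    )
    return ConcatenatedAlignment([f"m{i}" for i in range(n)], columns, matrix)


def mi_bruteforce(col_a, col_b):
    """Independent MI oracle: explicit loop over the joint frequency table."""
    pairs = [(a, b) for a, b in zip(col_a, col_b) if a not in "-X" and b not in "-X"]
    n = len(pairs)
    if n < 2:
        return None
    cj = Counter(pairs)
    ca = Counter(a for a, _ in pairs)
    cb = Counter(b for _, b in pairs)
    mi = 0.0
    for (a, b), c in cj.items():
        mi += (c / n) * math.log2(c * n / (ca[a] * cb[b]))
    return mi


@pytest.fixture(scope="session")
def planted_family():
    """One strongly coupled synthetic family, reused across tests."""
    from pdcovar.synthetic import FamilyConfig, PlantedPair, simulate_family

    cfg = FamilyConfig(planted_pairs=(PlantedPair(10, 3, 0.9),), seed=101)
    return simulate_family(cfg)
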