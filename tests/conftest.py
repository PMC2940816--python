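import numpy as np
import pandas as pd
import pytest

from helmscan.pathogen_env import PresenceMatrix
from helmscan.simulate import SimConfig, simulate_dataset


def brute_force_tau_b(x, y):
    """Independent O(n^2) pair-enumeration oracle for tau-b."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    C = D = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0:
                tx += 1
            if dy == 0:
                ty += 1
            if dx * dy > 0:
                C += 1
            elif dx * dy < 0:
                D += 1
    n0 = n * (n - 1) // 2
    if tx == n0 or ty == n0:
        return None  # degenerate
    return (C - D) / np.sqrt((n0 - tx) * (n0 - ty))


@pytest.fixture
def toy_presence():
    """3 species x 2 countries: sp1 everywhere, sp2 rare in its only
    country, sp3 absent."""
    present = pd.DataFrame(
        [[True, True], [True, False], [False, False]],
        index=["sp1", "sp2", "sp3"], columns=["c1", "c2"])
    rare = pd.DataFrame(
        [[False, False], [True, False], [False, False]],
        index=present.index, columns=present.columns)
    return PresenceMatrix(present=present, rare=rare)


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded small panel for pipeline-level tests: 10 countries x 3 pops,
    2,000 neutral + 20 planted SNPs, modest gene complement."""
    cfg = SimConfig(n_countries=10, pops_per_country=3, n_snps=2_000,
                    n_selected=20, n_genes=300, chrom_length=20_000_000,
                    target_set_size=40, seed=7)
    return simulate_dataset(cfg)
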