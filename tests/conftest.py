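import numpy as np
import pytest

from speqtl.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A compact planted dataset: 20 eQTL triples, 4 shared eGenes."""
    return SimConfig(
        seed=11,
        n_chroms=2,
        chrom_length=600_000,
        n_genes=40,
        n_snps_per_trait=40,
        n_identical_snps=6,
        n_tissues=2,
        samples_per_tissue=120,
        n_planted_cis=14,
        n_planted_trans=6,
        n_shared_egenes=4,
        n_coloc_loci_per_flag=1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# Independent oracles, used only to check the implementation
# ---------------------------------------------------------------------------

def bh_stepup_oracle(pvalues):
    """Brute-force Benjamini-Hochberg step-up adjustment."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def ols_slope_oracle(x, y):
    """Slope via the normal equations, written without scipy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())


def hypergeom_tail_oracle(k, big_n, big_k, n):
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), via math.comb."""
    from fractions import Fraction
    from math import comb

    total = comb(big_n, n)
    acc = Fraction(0)
    for j in range(max(k, 0), min(big_k, n) + 1):
        acc += Fraction(comb(big_k, j) * comb(big_n - big_k, n - j), total)
    return acc
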