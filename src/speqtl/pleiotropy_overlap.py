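"""Cross-trait overlap of SNP and eGene sets with bootstrap significance.

The observed overlap between two identifier sets is compared against a
resampling null: ``n_boot`` draws of ``size_a`` identifiers taken uniformly
without replacement from a universe, counting each draw's intersection with
the fixed second set.  That scheme samples exactly the
Hypergeometric(N, |B|, size_a) law, so its mean and variance are testable
in closed form.  Both a normal-fit upper-tail p (what overlap histograms
are usually annotated with) and the empirical p
``(1 + #{null >= observed}) / (n_boot + 1)`` are reported; the empirical
one is primary.

Identity is by rsID (or gene id) string — positions are not consulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("speqtl.overlap")


@dataclass
class OverlapResult:
    set_a_size: int
    set_b_size: int
    universe_size: int
    observed_overlap: int
    n_boot: int
    null_mean: float
    null_sd: float
    z: float
    p_normal: float
    p_empirical: float
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def overlap_sets(ids_a: Iterable[str], ids_b: Iterable[str]):
    """Exact set intersection; returns (shared_ids, observed_overlap)."""
    shared = set(ids_a) & set(ids_b)
    return shared, len(shared)


def shared_fraction(overlap: int, set_size: int) -> float:
    """Percentage ``100 * overlap / set_size`` rounded half-even to 1 decimal."""
    if set_size <= 0:
        raise ValueError("set_size must be > 0")
    if not (0 <= overlap <= set_size):
        raise ValueError("overlap must lie in [0, set_size]")
    return round(100.0 * overlap / set_size, 1)


def bootstrap_overlap(universe: Iterable[str], size_a: int,
                      fixed_set_b: Iterable[str], observed: int,
                      n_boot: int = 10_000,
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None) -> OverlapResult:
    """Bootstrap null for the overlap of a size-``size_a`` draw with set B.

    ``fixed_set_b`` must be a subset of ``universe`` and ``size_a`` cannot
    exceed the universe size.  The null mean/SD are fitted from the
    resampled counts (the normal fit); the empirical p uses the add-one
    rule so it is never zero.
    """
    universe = sorted(set(universe))
    b = set(fixed_set_b)
    if not b <= set(universe):
        raise ValueError("fixed_set_b must be a subset of the universe")
    n_universe = len(universe)
    if size_a > n_universe:
        raise ValueError(
            f"size_a={size_a} exceeds universe size {n_universe}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    b_mask = np.array([u in b for u in universe])
    counts = np.empty(n_boot, dtype=np.int64)
    for i in range(n_boot):
        idx = rng.choice(n_universe, size=size_a, replace=False)
        counts[i] = int(b_mask[idx].sum())

    null_mean = float(counts.mean())
    null_sd = float(counts.std(ddof=1)) if n_boot > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("inf")
    p_normal = float(stats.norm.sf(z)) if np.isfinite(z) else 0.0
    p_empirical = (1 + int((counts >= observed).sum())) / (n_boot + 1)
    return OverlapResult(
        set_a_size=size_a, set_b_size=len(b), universe_size=n_universe,
        observed_overlap=observed, n_boot=n_boot,
        null_mean=null_mean, null_sd=null_sd, z=float(z),
        p_normal=p_normal, p_empirical=float(p_empirical), seed=seed,
    )


def shared_egene_table(eqtls_a, eqtls_b, exclude_genes: Iterable[str] = ()) -> pd.DataFrame:
    """Genes with at least one significant eQTL from each trait.

    Both inputs must already be restricted to significant records.  Genes in
    ``exclude_genes`` (e.g. an HLA-style family list) are removed *before*
    overlap counting.  A shared gene is ``identical_snp_driven`` when every
    supporting eQTL in both traits carries one and the same rsID.
    """
    exclude = set(exclude_genes)

    def _by_gene(records):
        by: dict[str, set] = {}
        for r in records:
            if r.gene_id in exclude:
                continue
            by.setdefault(r.gene_id, set()).add(r.rsid)
        return by

    by_a = _by_gene(eqtls_a)
    by_b = _by_gene(eqtls_b)
    shared = sorted(set(by_a) & set(by_b))
    rows = []
    for gene in shared:
        all_rsids = by_a[gene] | by_b[gene]
        rows.append({
            "gene_id": gene,
            "rsids_a": ",".join(sorted(by_a[gene])),
            "rsids_b": ",".join(sorted(by_b[gene])),
            "n_eqtls_a": len(by_a[gene]),
            "n_eqtls_b": len(by_b[gene]),
            "identical_snp_driven": len(all_rsids) == 1,
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "rsids_a", "rsids_b", "n_eqtls_a", "n_eqtls_b",
        "identical_snp_driven",
    ])
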