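"""Tissue ranking, cross-trait direction-of-effect concordance, enrichment.

Enrichment is a one-sided hypergeometric over-representation test per gene
set, BH-corrected across all tested terms (a simpler, reproducible
correction than service-specific multiple-testing schemes; output headers
say BH).  The default background is the set of genes actually tested in
the eQTL stage, not the whole annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy import stats

from .eqtl_mapping import bh_adjust

logger = logging.getLogger("speqtl.reports")


@dataclass
class TissueSummary:
    tissue: str
    trait: str
    n_significant_triads: int
    n_samples: int
    rank: int


@dataclass
class ConcordanceRow:
    gene_id: str
    tissue: str
    trait_a_rsids: dict
    trait_b_rsids: dict
    direction: str


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int
    query_size: int
    intersection: int
    p: float
    fdr: float = float("nan")


def rank_tissues(eqtl_records, tissue_sample_sizes: dict, trait: str) -> list:
    """Rank tissues by count of significant SNP-gene-tissue triads.

    Only significant records are counted.  Ties are broken by tissue name
    (lexicographic) so ranks are deterministic; tissues with zero
    significant triads still appear, ranked last.
    """
    counts = {t: 0 for t in tissue_sample_sizes}
    for r in eqtl_records:
        if not r.significant:
            continue
        if r.tissue not in counts:
            raise KeyError(f"tissue {r.tissue!r} missing from sample-size table")
        counts[r.tissue] += 1
    ordered = sorted(counts, key=lambda t: (-counts[t], t))
    return [
        TissueSummary(
            tissue=t, trait=trait, n_significant_triads=counts[t],
            n_samples=int(tissue_sample_sizes[t]), rank=i + 1,
        )
        for i, t in enumerate(ordered)
    ]


def _sign(x: float) -> int:
    return 1 if x > 0 else (-1 if x < 0 else 0)


def direction_concordance(shared_gene_table: pd.DataFrame,
                          eqtls_a, eqtls_b) -> list:
    """Per (shared gene, tissue) direction-of-effect comparison.

    A cell needs at least one significant eQTL from each trait.  With the
    aFC sign sets A and B of the two traits: ``concordant`` when all signs
    in A and B agree on one direction; ``discordant`` when A and B are each
    internally consistent but opposite (e.g. several down-regulating
    variants in one trait against an up-regulating variant in the other);
    ``mixed`` otherwise.  Duplicated identical records do not change the
    call (signs are collected per rsID).
    """
    shared_genes = set(shared_gene_table["gene_id"])

    def _collect(records):
        cells: dict[tuple, dict] = {}
        for r in records:
            if not r.significant or r.gene_id not in shared_genes:
                continue
            cells.setdefault((r.gene_id, r.tissue), {})[r.rsid] = _sign(r.afc)
        return cells

    cells_a = _collect(eqtls_a)
    cells_b = _collect(eqtls_b)
    rows = []
    for key in sorted(set(cells_a) & set(cells_b)):
        signs_a = set(cells_a[key].values())
        signs_b = set(cells_b[key].values())
        if len(signs_a) == 1 and signs_a == signs_b:
            direction = "concordant"
        elif (len(signs_a) == 1 and len(signs_b) == 1
              and next(iter(signs_a)) == -next(iter(signs_b))):
            direction = "discordant"
        else:
            direction = "mixed"
        rows.append(ConcordanceRow(
            gene_id=key[0], tissue=key[1],
            trait_a_rsids=cells_a[key], trait_b_rsids=cells_b[key],
            direction=direction,
        ))
    return rows


def enrich_genesets(query_genes: Iterable[str], gmt_terms: dict,
                    background: Iterable[str],
                    alpha: float = 0.05) -> list:
    """Hypergeometric over-representation of ``query_genes`` in each term.

    Terms are intersected with the background first; terms disjoint from
    the background are dropped with a warning.  p = P(X >= k) with
    X ~ Hypergeometric(N=|background|, K=term_size, n=|query|), followed by
    BH across all tested terms.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    query = set(query_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")

    results: list[EnrichmentResult] = []
    n_dropped = 0
    big_n, small_n = len(background), len(query)
    for term_id in sorted(gmt_terms):
        term = set(gmt_terms[term_id]) & background
        if not term:
            n_dropped += 1
            continue
        k = len(term & query)
        p = float(stats.hypergeom.sf(k - 1, big_n, len(term), small_n))
        results.append(EnrichmentResult(
            term_id=term_id, term_size=len(term), query_size=small_n,
            intersection=k, p=min(p, 1.0),
        ))
    if n_dropped:
        logger.warning("dropped %d terms disjoint from the background", n_dropped)
    if results:
        fdrs = bh_adjust([r.p for r in results])
        for r, fdr in zip(results, fdrs):
            r.fdr = float(fdr)
    return results


def tissue_summary_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries], columns=[
        "tissue", "trait", "n_significant_triads", "n_samples", "rank",
    ])


def concordance_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "tissue": r.tissue,
        "trait_a_rsids": ",".join(f"{k}:{'+' if v > 0 else '-'}"
                                  for k, v in sorted(r.trait_a_rsids.items())),
        "trait_b_rsids": ",".join(f"{k}:{'+' if v > 0 else '-'}"
                                  for k, v in sorted(r.trait_b_rsids.items())),
        "direction": r.direction,
    } for r in rows], columns=[
        "gene_id", "tissue", "trait_a_rsids", "trait_b_rsids", "direction",
    ])


def enrichment_frame(results) -> pd.DataFrame:
    # header names advertise BH correction explicitly
    return pd.DataFrame([{
        "term_id": r.term_id, "term_size": r.term_size,
        "query_size": r.query_size, "intersection": r.intersection,
        "p_hypergeometric": r.p, "fdr_bh": r.fdr,
    } for r in results], columns=[
        "term_id", "term_size", "query_size", "intersection",
        "p_hypergeometric", "fdr_bh",
    ])
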