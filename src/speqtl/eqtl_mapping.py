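"""Per-tissue eQTL association testing, FDR control, and cis/trans classes.

Association is ordinary least squares of log2 expression on additive allele
dosage (0/1/2), with a two-sided t-test on the slope.  The slope on the
log2 scale is the allelic fold change (aFC) per alternative allele, whose
sign is the direction of eQTL effect.  Benjamini-Hochberg FDR is applied
once across all SNP-gene-tissue tests jointly (a conservative choice as the
test set grows); per-tissue scope is available via ``fdr_scope``.

Distance classes use the gene TSS as anchor:

* ``cis`` — same chromosome, |SNP - TSS| <= 1 Mb (boundary inclusive);
* ``trans_intra`` — same chromosome, > 1 Mb;
* ``trans_inter`` — different chromosomes (distance undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("speqtl.eqtl")

CIS_WINDOW = 1_000_000

EQTL_TSV_COLUMNS = [
    "rsid", "gene_id", "tissue", "beta", "se", "p", "fdr", "afc",
    "eqtl_class", "distance", "n", "significant", "flags",
]


class SkippedTest(Exception):
    """A SNP-gene-tissue test that cannot be performed; carries a reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class AssociationStats:
    beta: float
    se: float
    p: float
    n: int
    flag: Optional[str] = None


@dataclass
class EqtlRecord:
    rsid: str
    gene_id: str
    tissue: str
    beta: float
    se: float
    p: float
    afc: float
    n: int
    eqtl_class: str
    distance: Optional[int]
    fdr: float = float("nan")
    significant: bool = False
    flags: str = ""


def test_association(dosages, log2_expr, min_n: int = 10) -> AssociationStats:
    """OLS slope of log2 expression on dosage with a two-sided t-test.

    Missing values are dropped pairwise.  Raises :class:`SkippedTest` for a
    monomorphic SNP, constant expression, or fewer than ``min_n`` complete
    pairs.  A perfect fit (zero residual variance) gets the smallest
    positive normal float as p-value and the ``degenerate`` flag.
    """
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(log2_expr, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < min_n:
        raise SkippedTest("too_few_samples")
    if np.ptp(x) == 0:
        raise SkippedTest("zero_dosage_variance")
    if np.ptp(y) == 0:
        raise SkippedTest("zero_expr_variance")
    fit = stats.linregress(x, y)
    if not np.isfinite(fit.pvalue) or fit.stderr == 0:
        return AssociationStats(
            beta=float(fit.slope), se=float(fit.stderr),
            p=float(np.finfo(float).tiny), n=n, flag="degenerate",
        )
    return AssociationStats(
        beta=float(fit.slope), se=float(fit.stderr), p=float(fit.pvalue), n=n,
    )


def classify_pair(snp_chrom: str, snp_pos: int,
                  gene_chrom: str, gene_tss: int):
    """(eqtl_class, distance) for a SNP-gene pair; distance None across chroms."""
    if snp_chrom != gene_chrom:
        return "trans_inter", None
    distance = abs(snp_pos - gene_tss)
    return ("cis" if distance <= CIS_WINDOW else "trans_intra"), distance


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_eqtls(spatial_pairs, genotypes: dict, expression: dict,
               snps: Iterable, genes: Iterable,
               alpha: float = 0.05, min_samples: int = 10,
               fdr_scope: str = "global") -> list:
    """Test every spatial pair in every tissue and BH-adjust jointly.

    Parameters
    ----------
    spatial_pairs : list of SpatialPair
    genotypes : {tissue: DataFrame} dosage matrices (rsID x sample)
    expression : {tissue: DataFrame} log2 expression matrices (gene x sample)
    snps, genes : records providing coordinates for cis/trans classification
    fdr_scope : ``global`` (one BH run over all tissues, the default) or
        ``per-tissue``

    Every performable test is retained in the output with its FDR;
    ``significant`` flags fdr < alpha.  Tissues with fewer than
    ``min_samples`` samples are skipped with a warning, as are untestable
    records (monomorphic SNPs, constant expression), with reason tallies.
    """
    if fdr_scope not in ("global", "per-tissue"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    snp_by_id = {s.rsid: s for s in snps}
    gene_by_id = {g.gene_id: g for g in genes}

    records: list[EqtlRecord] = []
    skip_reasons: dict[str, int] = {}
    for tissue in sorted(expression):
        expr = expression[tissue]
        geno = genotypes[tissue]
        common = [s for s in expr.columns if s in set(geno.columns)]
        if len(common) < min_samples:
            logger.warning("tissue %s: only %d samples, skipped", tissue, len(common))
            continue
        ex = expr[common]
        gn = geno[common]
        for pair in spatial_pairs:
            snp = snp_by_id.get(pair.rsid)
            gene = gene_by_id.get(pair.gene_id)
            if snp is None or gene is None:
                skip_reasons["missing_annotation"] = skip_reasons.get(
                    "missing_annotation", 0) + 1
                continue
            if pair.rsid not in gn.index or pair.gene_id not in ex.index:
                skip_reasons["missing_data"] = skip_reasons.get("missing_data", 0) + 1
                continue
            try:
                assoc = test_association(
                    gn.loc[pair.rsid].to_numpy(),
                    ex.loc[pair.gene_id].to_numpy(),
                    min_n=min_samples,
                )
            except SkippedTest as exc:
                skip_reasons[exc.reason] = skip_reasons.get(exc.reason, 0) + 1
                continue
            eqtl_class, distance = classify_pair(
                snp.chrom, snp.pos, gene.chrom, gene.tss,
            )
            records.append(EqtlRecord(
                rsid=pair.rsid, gene_id=pair.gene_id, tissue=tissue,
                beta=assoc.beta, se=assoc.se, p=assoc.p, afc=assoc.beta,
                n=assoc.n, eqtl_class=eqtl_class, distance=distance,
                flags=assoc.flag or "",
            ))
    if skip_reasons:
        logger.info("skipped tests by reason: %s", skip_reasons)

    if not records:
        return records
    if fdr_scope == "global":
        groups = {None: records}
    else:
        groups = {}
        for r in records:
            groups.setdefault(r.tissue, []).append(r)
    for group in groups.values():
        fdrs = bh_adjust([r.p for r in group])
        for r, fdr in zip(group, fdrs):
            r.fdr = float(fdr)
            r.significant = bool(fdr < alpha)
    return records


def significant_records(records) -> list:
    return [r for r in records if r.significant]


def eqtls_from_frame(df: pd.DataFrame) -> list:
    """Inverse of :func:`eqtls_to_frame` (TSV round-trip)."""
    records = []
    for row in df.itertuples(index=False):
        dist = row.distance
        distance = None if (dist == "" or pd.isna(dist)) else int(float(dist))
        flags = "" if pd.isna(row.flags) else str(row.flags)
        records.append(EqtlRecord(
            rsid=row.rsid, gene_id=row.gene_id, tissue=row.tissue,
            beta=float(row.beta), se=float(row.se), p=float(row.p),
            afc=float(row.afc), n=int(row.n), eqtl_class=row.eqtl_class,
            distance=distance, fdr=float(row.fdr),
            significant=bool(row.significant), flags=flags,
        ))
    return records


def eqtls_to_frame(records) -> pd.DataFrame:
    """TSV-ready eQTL table with a fixed column order."""
    return pd.DataFrame([{
        "rsid": r.rsid, "gene_id": r.gene_id, "tissue": r.tissue,
        "beta": r.beta, "se": r.se, "p": r.p, "fdr": r.fdr, "afc": r.afc,
        "eqtl_class": r.eqtl_class,
        "distance": "" if r.distance is None else r.distance,
        "n": r.n, "significant": r.significant, "flags": r.flags,
    } for r in records], columns=EQTL_TSV_COLUMNS)
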