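"""Bayesian colocalization of two association signals over a locus.

For each SNP the Wakefield approximate Bayes factor against the null is
computed from the summary statistics alone:

    z = beta / se,  v = se^2,  r = w / (w + v)
    log ABF = 0.5 * (log(1 - r) + r * z^2)

where ``w`` is the prior variance of the true effect (0.15^2 for
quantitative traits, 0.2^2 for case-control log-odds scales).  With
per-SNP prior probabilities p1, p2 (causal for one trait only) and p12
(causal for both), the unnormalized hypothesis masses over a locus are

    S0 = 1
    S1 = p1 * sum_i ABF1_i
    S2 = p2 * sum_j ABF2_j
    S3 = p1 * p2 * (sum_i ABF1_i * sum_j ABF2_j - sum_i ABF1_i * ABF2_i)
    S4 = p12 * sum_i ABF1_i * ABF2_i

and PPk = Sk / sum(S) are the posterior probabilities of H0 (no
association) through H4 (one shared causal variant).  All sums run in log
space.  The model assumes a single causal variant per trait in the locus.

The colocalization call uses the published decision rule
PP3 + PP4 >= 0.99 together with PP4 / PP3 >= 5 (ratio treated as infinite
when PP3 is exactly zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger("speqtl.coloc")

DEFAULT_WINDOW = 200_000
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP causality priors and prior effect variances."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 5e-5
    w_quant: float = 0.15 ** 2
    w_cc: float = 0.2 ** 2

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.w_quant <= 0 or self.w_cc <= 0:
            raise ValueError("prior effect variances must be > 0")

    def w_for(self, trait_type: str) -> float:
        return self.w_cc if trait_type == "case_control" else self.w_quant


@dataclass(frozen=True)
class AbfRecord:
    rsid: str
    z: float
    v: float
    r: float
    labf: float


@dataclass
class ColocResult:
    locus_id: str
    lead_rsid: str
    n_snps: int
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    shared_causal_candidate: str
    colocalized: bool = False

    @property
    def posteriors(self):
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def extract_window(summary: pd.DataFrame, lead_rsid: str,
                   window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """SNPs within ``window`` bp of the lead SNP (inclusive), same chromosome."""
    lead = summary.loc[summary["rsid"] == lead_rsid]
    if lead.empty:
        raise KeyError(f"lead SNP {lead_rsid!r} not found in summary track")
    lead_chrom = lead["chrom"].iloc[0]
    lead_pos = int(lead["pos"].iloc[0])
    mask = (summary["chrom"] == lead_chrom) & (
        (summary["pos"] - lead_pos).abs() <= window
    )
    return summary.loc[mask].reset_index(drop=True)


def compute_labf(beta: float, se: float, w: float, rsid: str = "") -> AbfRecord:
    """Wakefield log approximate Bayes factor for one SNP."""
    if se <= 0:
        raise ValueError(f"{rsid}: se must be > 0")
    z = beta / se
    v = se * se
    r = w / (w + v)
    labf = 0.5 * (math.log1p(-r) + r * z * z)
    return AbfRecord(rsid=rsid, z=z, v=v, r=r, labf=labf)


def harmonize_tracks(track1: pd.DataFrame, track2: pd.DataFrame):
    """Inner-join two summary tracks on rsID, aligning alleles.

    If ref/alt columns are present and swapped between tracks, the second
    track's beta sign is flipped; strand-ambiguous (A/T, C/G) SNPs are
    dropped with a warning.  SNPs with irreconcilable alleles are dropped.
    """
    merged = track1.merge(track2, on="rsid", suffixes=("_1", "_2"))
    n_in = len(merged)
    if "ref_1" in merged.columns and "ref_2" in merged.columns:
        ambiguous = merged.apply(
            lambda r: (str(r["ref_1"]).upper(), str(r["alt_1"]).upper())
            in AMBIGUOUS_PAIRS, axis=1,
        )
        if ambiguous.any():
            logger.warning("dropped %d strand-ambiguous SNPs", int(ambiguous.sum()))
            merged = merged.loc[~ambiguous]
        same = (merged["ref_1"] == merged["ref_2"]) & (merged["alt_1"] == merged["alt_2"])
        flipped = (merged["ref_1"] == merged["alt_2"]) & (merged["alt_1"] == merged["ref_2"])
        merged = merged.loc[same | flipped].copy()
        merged.loc[flipped[same | flipped], "beta_2"] *= -1.0
    n_dropped = n_in - len(merged)
    if n_dropped:
        logger.info("allele harmonization dropped %d SNPs", n_dropped)
    return merged


def coloc_posteriors(labf1, labf2, rsids, priors: ColocPriors = ColocPriors(),
                     locus_id: str = "", lead_rsid: str = "") -> ColocResult:
    """PP0-PP4 from aligned per-SNP log-ABF tracks (same rsID order)."""
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    rsids = list(rsids)
    if not (len(labf1) == len(labf2) == len(rsids)):
        raise ValueError("labf tracks and rsids must be aligned")
    if len(rsids) == 0:
        raise ValueError("no_common_snps")

    l1 = float(logsumexp(labf1))
    l2 = float(logsumexp(labf2))
    l12 = float(logsumexp(labf1 + labf2))

    log_s = np.full(5, -np.inf)
    log_s[0] = 0.0
    log_s[1] = math.log(priors.p1) + l1
    log_s[2] = math.log(priors.p2) + l2
    # S3 = p1*p2*(L1*L2 - L12): log-space difference, floored at 0
    diff = l12 - (l1 + l2)
    if diff < 0:
        log_s[3] = (math.log(priors.p1) + math.log(priors.p2)
                    + l1 + l2 + math.log1p(-math.exp(diff)))
    log_s[4] = math.log(priors.p12) + l12

    total = float(logsumexp(log_s))
    pp = np.exp(log_s - total)

    candidate = rsids[int(np.argmax(labf1 + labf2))]
    result = ColocResult(
        locus_id=locus_id, lead_rsid=lead_rsid, n_snps=len(rsids),
        pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
        pp3=float(pp[3]), pp4=float(pp[4]),
        shared_causal_candidate=candidate,
    )
    result.colocalized = coloc_decision(result)
    return result


def coloc_decision(result: ColocResult) -> bool:
    """PP3 + PP4 >= 0.99 and PP4/PP3 >= 5 (infinite ratio when PP3 == 0)."""
    if result.pp3 + result.pp4 < 0.99:
        return False
    return result.pp4 >= 5.0 * result.pp3


def run_coloc(track1: pd.DataFrame, track2: pd.DataFrame, lead_rsid: str,
              window: int = DEFAULT_WINDOW,
              priors: ColocPriors = ColocPriors(),
              locus_id: str = "") -> ColocResult:
    """Window extraction, harmonization, ABF and posteriors for one locus.

    Each track carries its own ``trait_type`` column selecting the prior
    effect variance (quantitative vs case-control).
    """
    win1 = extract_window(track1, lead_rsid, window)
    win2 = extract_window(track2, lead_rsid, window)
    merged = harmonize_tracks(win1, win2)
    if merged.empty:
        raise ValueError("no_common_snps")
    w1 = priors.w_for(str(win1["trait_type"].iloc[0]))
    w2 = priors.w_for(str(win2["trait_type"].iloc[0]))
    labf1 = [compute_labf(b, s, w1).labf
             for b, s in zip(merged["beta_1"], merged["se_1"])]
    labf2 = [compute_labf(b, s, w2).labf
             for b, s in zip(merged["beta_2"], merged["se_2"])]
    logger.info("locus %s: %d SNPs after join", locus_id or lead_rsid, len(merged))
    return coloc_posteriors(
        labf1, labf2, merged["rsid"], priors,
        locus_id=locus_id or lead_rsid, lead_rsid=lead_rsid,
    )


def select_lowest_p_pairs(eqtl_records) -> dict:
    """Per SNP, keep the SNP-gene pair with the lowest p-value.

    Mirrors the pre-selection applied before colocalization when one eQTL
    track per lead SNP is needed.
    """
    best: dict[str, object] = {}
    for r in eqtl_records:
        if r.rsid not in best or r.p < best[r.rsid].p:
            best[r.rsid] = r
    return best
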