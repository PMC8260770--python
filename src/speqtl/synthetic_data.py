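"""Synthetic datasets with a planted-truth ledger.

Emulates the statistical structure of the pipeline's real-world inputs at
toy scale: two trait-associated SNP sets with a controlled number of
identical SNPs, a random genome digested into restriction fragments, Hi-C
contact libraries that support every planted SNP-gene effect, LD-blocked
genotypes in Hardy-Weinberg equilibrium, multi-tissue log2 expression with
planted cis/trans eQTL effects, and locus-level GWAS summary tracks with
shared vs distinct causal variants.

Planting is by construction: planted SNPs are *positioned* relative to
their target gene so cis/trans geometry is guaranteed, and a contact
between the SNP fragment and the gene fragment is always added (unless the
two coincide, in which case the same-fragment route applies).  Expression
is simulated directly on the log2 scale, so the planted effect size *is*
the allelic fold change the eQTL stage estimates.

Genotypes: per haplotype, alleles within an LD block share a latent
Gaussian factor (correlation ``ld_rho``) thresholded at the per-SNP allele
frequency; the two haplotypes are independent, so each SNP is exactly in
HWE while neighbouring SNPs are correlated.

Everything derives from a single :class:`numpy.random.Generator`, so equal
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import norm

from . import io_formats as iof
from .eqtl_mapping import classify_pair
from .fragments import digest

logger = logging.getLogger("speqtl.sim")

COLOC_FLAGS = ("shared_causal", "distinct_causal", "trait1_only", "null")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfig(BaseModel):
    """All knobs of the simulator, with testability-oriented defaults."""

    seed: int = 0
    n_chroms: int = Field(2, ge=1)
    chrom_length: int = Field(1_200_000, ge=1000)
    enzyme_motif: str = "GATC"
    cut_offset: int = 0
    n_genes: int = Field(60, ge=1)
    n_snps_per_trait: int = Field(80, ge=1)
    n_identical_snps: int = Field(12, ge=0)
    n_tissues: int = Field(3, ge=1)
    samples_per_tissue: int = Field(200, ge=2)
    n_planted_cis: int = Field(20, ge=0)
    n_planted_trans: int = Field(6, ge=0)
    afc_effect: float = 1.0
    noise_sd: float = Field(0.2, gt=0)
    maf_range: tuple[float, float] = (0.1, 0.45)
    ld_block_size: int = Field(5, ge=1)
    ld_rho: float = Field(0.8, ge=0, lt=1)
    contact_background_rate: float = Field(0.01, ge=0, le=1)
    n_shared_egenes: int = Field(8, ge=0)
    n_coloc_loci_per_flag: int = Field(2, ge=0)
    coloc_n_snps: int = Field(50, ge=2)
    coloc_gwas_n: int = Field(50_000, ge=10)
    trait_names: tuple[str, str] = ("trait1", "trait2")

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 0.5")
        if self.n_identical_snps > self.n_snps_per_trait:
            raise ValueError("n_identical_snps cannot exceed n_snps_per_trait")
        n_unique = 2 * self.n_snps_per_trait - self.n_identical_snps
        if 2 * self.n_shared_egenes > self.n_planted_cis:
            raise ValueError(
                "each planted shared eGene consumes two cis triples: need "
                f"n_planted_cis >= {2 * self.n_shared_egenes}"
            )
        n_triples = self.n_planted_cis + self.n_planted_trans
        if n_triples > n_unique:
            raise ValueError("more planted eQTL triples than available SNPs")
        genes_needed = (self.n_planted_cis - 2 * self.n_shared_egenes
                        + self.n_planted_trans + self.n_shared_egenes)
        if genes_needed > self.n_genes:
            raise ValueError("more planted eQTL triples than available genes")
        if self.n_shared_egenes > 0:
            per_trait_specific = self.n_snps_per_trait - self.n_identical_snps
            if self.n_shared_egenes > per_trait_specific:
                raise ValueError(
                    "n_shared_egenes exceeds trait-specific SNPs per trait"
                )
        if self.n_planted_trans > 0 and self.n_chroms < 2 \
                and self.chrom_length <= 2_000_000:
            raise ValueError(
                "trans planting needs >= 2 chromosomes or a chromosome "
                "longer than 2 Mb"
            )
        return self


@dataclass(frozen=True)
class PlantedEqtl:
    rsid: str
    gene_id: str
    tissue: str
    afc: float
    eqtl_class: str


@dataclass(frozen=True)
class PlantedLocus:
    locus_id: str
    flag: str
    causal_trait1: Optional[str]
    causal_trait2: Optional[str]


@dataclass
class TruthLedger:
    """Planted effects enabling parameter-recovery tests downstream."""

    eqtls: list = field(default_factory=list)
    contacts: list = field(default_factory=list)      # (frag_a, frag_b)
    shared_egenes: list = field(default_factory=list)
    identical_snps: list = field(default_factory=list)
    coloc_loci: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "eqtls": [asdict(e) for e in self.eqtls],
            "contacts": [list(c) for c in self.contacts],
            "shared_egenes": list(self.shared_egenes),
            "identical_snps": list(self.identical_snps),
            "coloc_loci": [asdict(l) for l in self.coloc_loci],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        return cls(
            eqtls=[PlantedEqtl(**e) for e in payload["eqtls"]],
            contacts=[tuple(c) for c in payload["contacts"]],
            shared_egenes=payload["shared_egenes"],
            identical_snps=payload["identical_snps"],
            coloc_loci=[PlantedLocus(**l) for l in payload["coloc_loci"]],
        )


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict
    fragment_map: object
    genes: list
    snp_sets: dict            # trait -> list[SnpRecord]
    snps: list                # unique SNPs, both traits
    contacts: list
    genotypes: dict           # tissue -> DataFrame (rsid x sample)
    expression: dict          # tissue -> DataFrame (gene x sample)
    gwas: dict                # trait -> DataFrame
    truth: TruthLedger

    @property
    def tissue_sample_sizes(self) -> dict:
        return {t: df.shape[1] for t, df in self.expression.items()}


# ---------------------------------------------------------------------------
# coloc locus simulator
# ---------------------------------------------------------------------------

@dataclass
class ColocLocusSim:
    track1: pd.DataFrame
    track2: pd.DataFrame
    flag: str
    causal_trait1: Optional[str]
    causal_trait2: Optional[str]


def _null_z(rng, size: int) -> np.ndarray:
    """Standard-normal draws, redrawn above |z| = 6 so a planted causal
    variant always carries the locus minimum p-value by construction."""
    z = rng.normal(0.0, 1.0, size=size)
    bad = np.abs(z) >= 6.0
    while bad.any():
        z[bad] = rng.normal(0.0, 1.0, size=int(bad.sum()))
        bad = np.abs(z) >= 6.0
    return z


def _causal_z(rng, z_causal: float) -> float:
    z = rng.normal(z_causal, 0.5)
    while z <= 6.5:
        z = rng.normal(z_causal, 0.5)
    return float(z)


def simulate_coloc_locus(flag: str, n_snps: int = 50, n_gwas: int = 50_000,
                         seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None,
                         chrom: str = "chrL", locus_id: str = "locus",
                         spacing: int = 1000,
                         z_causal: float = 8.0,
                         trait_type: str = "case_control") -> ColocLocusSim:
    """Two GWAS summary tracks over one locus under a planted scenario.

    Under the single-causal-variant regime the coloc model assumes,
    non-causal z-scores are independent standard normal; the causal SNP
    gets z ~ z_causal.  ``shared_causal`` plants the same causal SNP in
    both tracks, ``distinct_causal`` two different ones, ``trait1_only``
    leaves track 2 null, and ``null`` leaves both null.
    """
    if flag not in COLOC_FLAGS:
        raise ValueError(f"unknown coloc flag {flag!r}")
    if n_snps < 2:
        raise ValueError("n_snps must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)

    se = 1.0 / np.sqrt(n_gwas)
    rsids = [f"{locus_id}_rs{i + 1}" for i in range(n_snps)]
    positions = np.arange(n_snps) * spacing

    z1 = _null_z(rng, n_snps)
    z2 = _null_z(rng, n_snps)
    causal1 = causal2 = None
    if flag in ("shared_causal", "distinct_causal", "trait1_only"):
        i1 = int(rng.integers(n_snps))
        z1[i1] = _causal_z(rng, z_causal)
        causal1 = rsids[i1]
    if flag == "shared_causal":
        z2[i1] = _causal_z(rng, z_causal)
        causal2 = rsids[i1]
    elif flag == "distinct_causal":
        i2 = int(rng.integers(n_snps - 1))
        if i2 >= i1:
            i2 += 1
        z2[i2] = _causal_z(rng, z_causal)
        causal2 = rsids[i2]

    def _track(z):
        rows = [iof.GwasSummaryRow(
            rsid=rsids[i], chrom=chrom, pos=int(positions[i]),
            beta=float(z[i] * se), se=float(se),
            p=float(2.0 * norm.sf(abs(z[i]))), n=n_gwas,
            trait_type=trait_type, ref="A", alt="G",
        ) for i in range(n_snps)]
        return iof.gwas_rows_to_frame(rows, locus_id=locus_id)

    return ColocLocusSim(
        track1=_track(z1), track2=_track(z2), flag=flag,
        causal_trait1=causal1, causal_trait2=causal2,
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _block_assignment(ordered, ld_block_size: int) -> np.ndarray:
    """Block index per SNP: consecutive runs of ld_block_size per chromosome.

    ``ordered`` is (chrom, pos) sorted; used both for genotype simulation and
    for keeping co-causal SNP pairs out of one block.
    """
    block_of = np.empty(len(ordered), dtype=np.int64)
    block = -1
    prev_chrom, in_block = None, 0
    for i, s in enumerate(ordered):
        if s[0] != prev_chrom or in_block == ld_block_size:
            block += 1
            in_block = 0
            prev_chrom = s[0]
        block_of[i] = block
        in_block += 1
    return block_of


def _simulate_genotypes(rng, snps, mafs: dict, samples: list,
                        ld_block_size: int, ld_rho: float) -> pd.DataFrame:
    """LD-blocked dosages under HWE via a shared latent Gaussian per block."""
    ordered = sorted(snps, key=lambda s: (s.chrom, s.pos))
    n_snps, n_samples = len(ordered), len(samples)
    block_of = _block_assignment([(s.chrom, s.pos) for s in ordered],
                                 ld_block_size)
    n_blocks = int(block_of[-1]) + 1

    thresholds = norm.ppf(np.array([mafs[s.rsid] for s in ordered]))
    dosage = np.zeros((n_snps, n_samples), dtype=np.int8)
    for _hap in range(2):
        latent = rng.normal(size=(n_blocks, n_samples))
        eps = rng.normal(size=(n_snps, n_samples))
        x = (np.sqrt(ld_rho) * latent[block_of]
             + np.sqrt(1.0 - ld_rho) * eps)
        dosage += (x < thresholds[:, None]).astype(np.int8)
    return pd.DataFrame(dosage.astype(float), index=[s.rsid for s in ordered],
                        columns=samples)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def _random_genome(rng, config: SimConfig) -> dict:
    genome = {}
    for c in range(config.n_chroms):
        idx = rng.integers(0, 4, size=config.chrom_length)
        genome[f"chr{c + 1}"] = _BASES[idx].tobytes().decode("ascii")
    return genome


def _place_genes(rng, config: SimConfig, genome: dict) -> list:
    genes = []
    chroms = sorted(genome)
    for i in range(config.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1000, 5001))
        start = int(rng.integers(0, len(genome[chrom]) - length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(iof.GeneRecord(
            gene_id=f"GENE{i + 1:04d}", name=f"G{i + 1}", chrom=chrom,
            start=start, end=start + length, strand=strand,
        ))
    return genes


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a complete, internally consistent dataset plus truth ledger."""
    rng = np.random.default_rng(config.seed)
    t1, t2 = config.trait_names

    genome = _random_genome(rng, config)
    fmap = digest(genome, config.enzyme_motif, config.cut_offset)
    genes = _place_genes(rng, config, genome)
    chroms = sorted(genome)

    # --- SNP scaffold: ids and trait membership ---------------------------
    n_unique = 2 * config.n_snps_per_trait - config.n_identical_snps
    rsids = [f"rs{i + 1}" for i in range(n_unique)]
    n_shared_snp = config.n_identical_snps
    traits_of = {}
    for i, rsid in enumerate(rsids):
        if i < n_shared_snp:
            traits_of[rsid] = frozenset({t1, t2})
        elif i < n_shared_snp + (config.n_snps_per_trait - n_shared_snp):
            traits_of[rsid] = frozenset({t1})
        else:
            traits_of[rsid] = frozenset({t2})
    pool_t1 = [r for r in rsids if traits_of[r] == frozenset({t1})]
    pool_t2 = [r for r in rsids if traits_of[r] == frozenset({t2})]
    pool_any = list(rsids)

    # --- planted triples (positions assigned by construction) -------------
    tissues = [f"tissue{i + 1}" for i in range(config.n_tissues)]
    gene_order = list(rng.permutation(len(genes)))
    used_snps: set[str] = set()
    planted: list[dict] = []  # rsid, gene_idx, tissue, afc, kind

    def _take(pool: list) -> str:
        for r in pool:
            if r not in used_snps:
                used_snps.add(r)
                return r
        raise RuntimeError("SNP pool exhausted")  # guarded by SimConfig

    def _rand_sign() -> float:
        return 1.0 if rng.random() < 0.5 else -1.0

    shared_egene_ids = []
    shared_snp_pairs = []  # (rsid_t1, rsid_t2, gene_idx) co-causal for a gene
    gi = 0
    for _ in range(config.n_shared_egenes):
        g = gene_order[gi]; gi += 1
        tissue = tissues[int(rng.integers(len(tissues)))]
        shared_egene_ids.append(genes[g].gene_id)
        pair = []
        for pool in (pool_t1, pool_t2):
            rsid = _take(pool)
            pair.append(rsid)
            planted.append({
                "rsid": rsid, "gene_idx": g, "tissue": tissue,
                "afc": _rand_sign() * config.afc_effect, "kind": "cis",
            })
        shared_snp_pairs.append((pair[0], pair[1], g))
    for _ in range(config.n_planted_cis - 2 * config.n_shared_egenes):
        g = gene_order[gi]; gi += 1
        planted.append({
            "rsid": _take(pool_any), "gene_idx": g,
            "tissue": tissues[int(rng.integers(len(tissues)))],
            "afc": _rand_sign() * config.afc_effect, "kind": "cis",
        })
    for _ in range(config.n_planted_trans):
        g = gene_order[gi]; gi += 1
        planted.append({
            "rsid": _take(pool_any), "gene_idx": g,
            "tissue": tissues[int(rng.integers(len(tissues)))],
            "afc": _rand_sign() * config.afc_effect, "kind": "trans",
        })

    # --- SNP positions -----------------------------------------------------
    taken: set[tuple] = set()

    def _unique_pos(chrom: str, lo: int, hi: int) -> int:
        while True:
            pos = int(rng.integers(lo, hi))
            if (chrom, pos) not in taken:
                taken.add((chrom, pos))
                return pos

    snp_loc: dict[str, tuple] = {}
    for p in planted:
        gene = genes[p["gene_idx"]]
        if p["kind"] == "cis":
            chrom = gene.chrom
            L = len(genome[chrom])
            lo = max(0, gene.tss - 1_000_000)
            hi = min(L, gene.tss + 1_000_000 + 1)
            snp_loc[p["rsid"]] = (chrom, _unique_pos(chrom, lo, hi))
        else:
            others = [c for c in chroms if c != gene.chrom]
            if others:
                chrom = others[int(rng.integers(len(others)))]
                snp_loc[p["rsid"]] = (chrom, _unique_pos(chrom, 0, len(genome[chrom])))
            else:  # single long chromosome: place > 1 Mb from the TSS
                chrom = gene.chrom
                L = len(genome[chrom])
                lo_side = gene.tss - 1_000_001 > 0
                if lo_side and rng.random() < 0.5:
                    snp_loc[p["rsid"]] = (chrom, _unique_pos(chrom, 0, gene.tss - 1_000_000))
                else:
                    snp_loc[p["rsid"]] = (chrom, _unique_pos(chrom, gene.tss + 1_000_001, L))
    for rsid in rsids:
        if rsid not in snp_loc:
            chrom = chroms[int(rng.integers(len(chroms)))]
            snp_loc[rsid] = (chrom, _unique_pos(chrom, 0, len(genome[chrom])))

    # Two SNPs planted on one gene must not share an LD block, otherwise
    # their correlated dosages bias each other's marginal effect estimate.
    def _block_of_rsid():
        order = sorted(rsids, key=lambda r: snp_loc[r])
        blocks = _block_assignment([snp_loc[r] for r in order],
                                   config.ld_block_size)
        return dict(zip(order, blocks))

    for _attempt in range(100):
        blocks = _block_of_rsid()
        clashes = [(ra, rb, g) for ra, rb, g in shared_snp_pairs
                   if blocks[ra] == blocks[rb]]
        if not clashes:
            break
        for _ra, rb, g in clashes:
            gene = genes[g]
            taken.discard(snp_loc[rb])
            L = len(genome[gene.chrom])
            lo = max(0, gene.tss - 1_000_000)
            hi = min(L, gene.tss + 1_000_000 + 1)
            snp_loc[rb] = (gene.chrom, _unique_pos(gene.chrom, lo, hi))
    else:
        raise RuntimeError("could not decorrelate co-causal SNP pairs")

    base_pairs = ["A", "C", "G", "T"]
    snps = []
    for rsid in rsids:
        chrom, pos = snp_loc[rsid]
        ref = base_pairs[int(rng.integers(4))]
        alt = [b for b in base_pairs if b != ref][int(rng.integers(3))]
        snps.append(iof.SnpRecord(rsid=rsid, chrom=chrom, pos=pos, ref=ref,
                                  alt=alt, traits=traits_of[rsid]))
    snp_by_id = {s.rsid: s for s in snps}
    snp_sets = {
        t1: [s for s in snps if t1 in s.traits],
        t2: [s for s in snps if t2 in s.traits],
    }

    # --- truth: planted eQTLs with geometry-derived classes ----------------
    truth = TruthLedger(
        shared_egenes=shared_egene_ids,
        identical_snps=rsids[:n_shared_snp],
    )
    for p in planted:
        snp = snp_by_id[p["rsid"]]
        gene = genes[p["gene_idx"]]
        eqtl_class, _dist = classify_pair(snp.chrom, snp.pos, gene.chrom, gene.tss)
        truth.eqtls.append(PlantedEqtl(
            rsid=snp.rsid, gene_id=gene.gene_id, tissue=p["tissue"],
            afc=p["afc"], eqtl_class=eqtl_class,
        ))

    # --- contacts ----------------------------------------------------------
    libraries = ["hic_libA", "hic_libB"]
    contact_counts: dict[tuple, int] = {}
    planted_pairs: set[tuple] = set()
    for p in planted:
        snp = snp_by_id[p["rsid"]]
        gene = genes[p["gene_idx"]]
        fs = fmap.fragment_at(snp.chrom, snp.pos)
        fg = fmap.fragment_at(gene.chrom, gene.tss)
        if fs == fg:
            continue  # same-fragment pairs are emitted without a contact
        key = (min(fs, fg), max(fs, fg))
        planted_pairs.add(key)
        lib = libraries[int(rng.integers(len(libraries)))]
        contact_counts[(lib, *key)] = contact_counts.get((lib, *key), 0) \
            + int(rng.integers(1, 4))
        if rng.random() < 0.3:  # some pairs seen in both libraries
            other = libraries[1 - libraries.index(lib)]
            contact_counts[(other, *key)] = contact_counts.get((other, *key), 0) + 1
        truth.contacts.append(key)

    snp_frags = sorted({fmap.fragment_at(s.chrom, s.pos) for s in snps})
    gene_frags = sorted({fmap.fragment_at(g.chrom, g.tss) for g in genes})
    n_bg = int(round(config.contact_background_rate
                     * len(snp_frags) * len(gene_frags)))
    for _ in range(n_bg):
        fs = snp_frags[int(rng.integers(len(snp_frags)))]
        fg = gene_frags[int(rng.integers(len(gene_frags)))]
        if fs == fg:
            continue
        key = (min(fs, fg), max(fs, fg))
        if key in planted_pairs:
            continue
        lib = libraries[int(rng.integers(len(libraries)))]
        contact_counts[(lib, *key)] = contact_counts.get((lib, *key), 0) + 1
    contacts = [
        iof.ContactPair(library_id=lib, frag_a=fa, frag_b=fb, count=c)
        for (lib, fa, fb), c in sorted(contact_counts.items())
    ]

    # --- genotypes and expression ------------------------------------------
    lo, hi = config.maf_range
    mafs = {rsid: float(rng.uniform(lo, hi)) for rsid in rsids}
    genotypes, expression = {}, {}
    planted_by_tissue: dict[str, list] = {}
    for e in truth.eqtls:
        planted_by_tissue.setdefault(e.tissue, []).append(e)
    gene_ids = [g.gene_id for g in genes]
    for tissue in tissues:
        samples = [f"{tissue}_s{i + 1:03d}" for i in range(config.samples_per_tissue)]
        geno = _simulate_genotypes(rng, snps, mafs, samples,
                                   config.ld_block_size, config.ld_rho)
        baseline = rng.normal(5.0, 1.0, size=len(gene_ids))
        expr = np.repeat(baseline[:, None], len(samples), axis=1).copy()
        for e in planted_by_tissue.get(tissue, []):
            gidx = gene_ids.index(e.gene_id)
            expr[gidx] += e.afc * geno.loc[e.rsid].to_numpy()
        expr += rng.normal(0.0, config.noise_sd, size=expr.shape)
        genotypes[tissue] = geno
        expression[tissue] = pd.DataFrame(expr, index=gene_ids, columns=samples)

    # --- coloc loci ---------------------------------------------------------
    gwas_frames = {t1: [], t2: []}
    k = 0
    for flag in COLOC_FLAGS:
        for _ in range(config.n_coloc_loci_per_flag):
            k += 1
            locus_id = f"locus{k:02d}_{flag}"
            sim = simulate_coloc_locus(
                flag, n_snps=config.coloc_n_snps, n_gwas=config.coloc_gwas_n,
                rng=rng, chrom=f"chrL{k}", locus_id=locus_id,
            )
            gwas_frames[t1].append(sim.track1)
            gwas_frames[t2].append(sim.track2)
            truth.coloc_loci.append(PlantedLocus(
                locus_id=locus_id, flag=flag,
                causal_trait1=sim.causal_trait1, causal_trait2=sim.causal_trait2,
            ))
    gwas = {
        t: (pd.concat(frames, ignore_index=True) if frames else pd.DataFrame())
        for t, frames in gwas_frames.items()
    }

    assert len(truth.eqtls) == config.n_planted_cis + config.n_planted_trans
    return SimulatedDataset(
        config=config, genome=genome, fragment_map=fmap, genes=genes,
        snp_sets=snp_sets, snps=snps, contacts=contacts,
        genotypes=genotypes, expression=expression, gwas=gwas, truth=truth,
    )


def demo_gene_sets(ds: SimulatedDataset, n_terms: int = 6) -> dict:
    """Small GMT-style term collection over the simulated genes.

    One term collects the planted shared eGenes (plus a little padding) so
    over-representation of the recovered shared genes is detectable; the
    rest are random gene sets.  Deterministic given the dataset's seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([ds.config.seed, 97]))
    gene_ids = [g.gene_id for g in ds.genes]
    terms = {}
    pad = [g for g in gene_ids if g not in set(ds.truth.shared_egenes)]
    n_pad = min(3, len(pad))
    pick = list(rng.choice(len(pad), size=n_pad, replace=False)) if n_pad else []
    terms["TERM_PLANTED_SHARED"] = set(ds.truth.shared_egenes) | {pad[i] for i in pick}
    for k in range(n_terms - 1):
        size = int(rng.integers(5, max(6, len(gene_ids) // 3)))
        size = min(size, len(gene_ids))
        idx = rng.choice(len(gene_ids), size=size, replace=False)
        terms[f"TERM_RANDOM_{k + 1}"] = {gene_ids[i] for i in idx}
    return terms


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write every component in the formats the readers expect.

    Returns {name: path}.  Output is deterministic given the dataset.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["genome"] = outdir / "genome.fa"
    iof.write_fasta(ds.genome, paths["genome"])
    paths["genes"] = outdir / "genes.gff3"
    iof.write_gff_genes(ds.genes, paths["genes"])
    paths["fragments"] = outdir / "fragments.bed"
    ds.fragment_map.to_bed(paths["fragments"])
    for trait, snps in ds.snp_sets.items():
        paths[f"snps_{trait}"] = outdir / f"snps_{trait}.tsv"
        iof.write_snp_table(snps, paths[f"snps_{trait}"])
    paths["contacts"] = outdir / "contacts.bedpe"
    iof.write_contacts_bedpe(ds.contacts, ds.fragment_map, paths["contacts"])
    for tissue, geno in ds.genotypes.items():
        paths[f"genotypes_{tissue}"] = outdir / f"genotypes_{tissue}.vcf"
        iof.write_vcf_genotypes(geno, ds.snps, paths[f"genotypes_{tissue}"])
        paths[f"expression_{tissue}"] = outdir / f"expression_{tissue}.tsv"
        ds.expression[tissue].to_csv(paths[f"expression_{tissue}"], sep="\t",
                                     index_label="gene_id")
    for trait, df in ds.gwas.items():
        paths[f"gwas_{trait}"] = outdir / f"gwas_{trait}.tsv"
        iof.write_gwas_summary(df, paths[f"gwas_{trait}"])
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    iof.write_gmt(demo_gene_sets(ds), paths["gene_sets"])
    paths["truth"] = outdir / "truth.json"
    ds.truth.to_json(paths["truth"])
    return paths
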