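"""End-to-end orchestration: simulate → digest → pairs → eqtl → overlap →
coloc → report, driven by one YAML config, with a manifest of outputs.

Each stage writes its outputs before the next starts, so a failure in
stage *k* preserves everything from stages < *k*.  One structured log line
records every decision the analysis leaves implicit (bootstrap universe
size, dropped SNPs, joined coloc SNP counts) so the run is auditable.
Re-running with the same config and seed reproduces identical file
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from . import io_formats as iof
from .colocalization import ColocPriors, run_coloc
from .downstream_reports import (
    concordance_frame, direction_concordance, enrich_genesets,
    enrichment_frame, rank_tissues, tissue_summary_frame,
)
from .eqtl_mapping import call_eqtls, eqtls_to_frame, significant_records
from .fragments import digest
from .pleiotropy_overlap import (
    bootstrap_overlap, overlap_sets, shared_egene_table,
)
from .spatial_pairs import find_spatial_pairs, pair_statistics, pairs_to_frame
from .synthetic_data import SimConfig, simulate_dataset, write_dataset

logger = logging.getLogger("speqtl.pipeline")

STAGES = ["simulate", "digest", "pairs", "eqtl", "overlap", "coloc", "report"]


class DigestParams(BaseModel):
    enzyme_motif: str = "GATC"
    cut_offset: int = 0


class PairsParams(BaseModel):
    gene_anchor: str = "tss"


class EqtlParams(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    min_samples: int = Field(10, ge=2)
    fdr_scope: str = "global"


class OverlapParams(BaseModel):
    n_boot: int = Field(10_000, ge=1)
    exclude_genes: list[str] = Field(default_factory=list)


class ColocParams(BaseModel):
    window: int = Field(200_000, ge=0)
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 5e-5


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: str = "speqtl_run"
    simulate: SimConfig = Field(default_factory=SimConfig)
    digest: DigestParams = Field(default_factory=DigestParams)
    pairs: PairsParams = Field(default_factory=PairsParams)
    eqtl: EqtlParams = Field(default_factory=EqtlParams)
    overlap: OverlapParams = Field(default_factory=OverlapParams)
    coloc: ColocParams = Field(default_factory=ColocParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict, seconds: float) -> None:
        self.stages.append({
            "name": name,
            "outputs": {str(p): _sha256(p) for p in outputs.values()},
            "seconds": round(seconds, 3),
        })

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class PipelineResult:
    manifest: RunManifest
    dataset: object = None
    eqtls: dict = field(default_factory=dict)          # trait -> records
    shared_genes: Optional[pd.DataFrame] = None
    overlap: dict = field(default_factory=dict)        # name -> OverlapResult
    coloc: list = field(default_factory=list)
    outdir: Optional[Path] = None


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute all stages in dependency order and write a manifest last."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, version=__version__,
    )
    result = PipelineResult(manifest=manifest, outdir=outdir)
    sim_config = config.simulate.model_copy(update={"seed": config.seed})
    t1, t2 = sim_config.trait_names
    state: dict = {}

    def _stage(name, fn):
        start = time.perf_counter()
        try:
            outputs = fn()
        except Exception as exc:  # noqa: BLE001 — manifest must name the stage
            raise StageError(name, exc) from exc
        manifest.add_stage(name, outputs, time.perf_counter() - start)
        logger.info("stage %s done (%d outputs)", name, len(outputs))

    # -- simulate ----------------------------------------------------------
    def _simulate():
        ds = simulate_dataset(sim_config)
        state["ds"] = ds
        result.dataset = ds
        return write_dataset(ds, outdir / "inputs")

    _stage("simulate", _simulate)
    ds = state["ds"]

    # -- digest ------------------------------------------------------------
    def _digest():
        fmap = digest(ds.genome, config.digest.enzyme_motif,
                      config.digest.cut_offset)
        state["fmap"] = fmap
        path = outdir / "fragments.bed"
        fmap.to_bed(path)
        return {"fragments": path}

    _stage("digest", _digest)
    fmap = state["fmap"]

    # -- pairs -------------------------------------------------------------
    def _pairs():
        outputs = {}
        state["pairs"] = {}
        for trait in (t1, t2):
            pairs = find_spatial_pairs(
                ds.snp_sets[trait], ds.genes, fmap, ds.contacts,
                gene_anchor=config.pairs.gene_anchor,
            )
            state["pairs"][trait] = pairs
            stats = pair_statistics(pairs)
            logger.info("trait %s: %d spatial pairs (%d same-fragment)",
                        trait, stats["n_pairs"], stats["n_same_fragment"])
            path = outdir / f"spatial_pairs_{trait}.tsv"
            pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
            outputs[trait] = path
        return outputs

    _stage("pairs", _pairs)

    # -- eqtl --------------------------------------------------------------
    def _eqtl():
        outputs = {}
        for trait in (t1, t2):
            records = call_eqtls(
                state["pairs"][trait], ds.genotypes, ds.expression,
                ds.snps, ds.genes,
                alpha=config.eqtl.alpha, min_samples=config.eqtl.min_samples,
                fdr_scope=config.eqtl.fdr_scope,
            )
            result.eqtls[trait] = records
            path = outdir / f"eqtls_{trait}.tsv"
            eqtls_to_frame(records).to_csv(path, sep="\t", index=False)
            outputs[trait] = path
        return outputs

    _stage("eqtl", _eqtl)

    # -- overlap -----------------------------------------------------------
    def _overlap():
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2]))
        snps_a = {s.rsid for s in ds.snp_sets[t1]}
        snps_b = {s.rsid for s in ds.snp_sets[t2]}
        universe = sorted(snps_a | snps_b)
        _shared, observed = overlap_sets(snps_a, snps_b)
        logger.info("SNP overlap universe size %d", len(universe))
        snp_overlap = bootstrap_overlap(
            universe, len(snps_a), snps_b, observed,
            n_boot=config.overlap.n_boot, rng=rng,
        )
        result.overlap["snps"] = snp_overlap

        sig_a = significant_records(result.eqtls[t1])
        sig_b = significant_records(result.eqtls[t2])
        exclude = set(config.overlap.exclude_genes)
        shared = shared_egene_table(sig_a, sig_b, exclude)
        result.shared_genes = shared
        egenes_a = {r.gene_id for r in sig_a} - exclude
        egenes_b = {r.gene_id for r in sig_b} - exclude
        tested = sorted(({r.gene_id for r in result.eqtls[t1]}
                         | {r.gene_id for r in result.eqtls[t2]}) - exclude)
        logger.info("gene overlap universe (tested genes) size %d", len(tested))
        gene_overlap = bootstrap_overlap(
            tested, len(egenes_a), egenes_b, len(shared),
            n_boot=config.overlap.n_boot, rng=rng,
        )
        result.overlap["egenes"] = gene_overlap

        shared_path = outdir / "shared_egenes.tsv"
        shared.to_csv(shared_path, sep="\t", index=False)
        overlap_path = outdir / "overlap_results.json"
        overlap_path.write_text(json.dumps({
            "snps": snp_overlap.to_dict(),
            "egenes": gene_overlap.to_dict(),
        }, indent=1, sort_keys=True))
        return {"shared_egenes": shared_path, "overlap": overlap_path}

    _stage("overlap", _overlap)

    # -- coloc -------------------------------------------------------------
    def _coloc():
        priors = ColocPriors(p1=config.coloc.p1, p2=config.coloc.p2,
                             p12=config.coloc.p12)
        rows = []
        track1, track2 = ds.gwas[t1], ds.gwas[t2]
        if not track1.empty:
            for locus_id, sub1 in track1.groupby("locus_id", sort=True):
                sub2 = track2[track2["locus_id"] == locus_id]
                lead = sub1.loc[sub1["p"].idxmin(), "rsid"]
                res = run_coloc(sub1, sub2, lead, window=config.coloc.window,
                                priors=priors, locus_id=locus_id)
                result.coloc.append(res)
                rows.append(res.to_dict())
        path = outdir / "coloc_results.tsv"
        pd.DataFrame(rows, columns=[
            "locus_id", "lead_rsid", "n_snps", "pp0", "pp1", "pp2", "pp3",
            "pp4", "shared_causal_candidate", "colocalized",
        ]).to_csv(path, sep="\t", index=False)
        return {"coloc": path}

    _stage("coloc", _coloc)

    # -- report ------------------------------------------------------------
    def _report():
        outputs = {}
        sizes = ds.tissue_sample_sizes
        summaries = []
        for trait in (t1, t2):
            summaries.extend(rank_tissues(result.eqtls[trait], sizes, trait))
        path = outdir / "tissue_ranking.tsv"
        tissue_summary_frame(summaries).to_csv(path, sep="\t", index=False)
        outputs["tissues"] = path

        conc = direction_concordance(
            result.shared_genes,
            significant_records(result.eqtls[t1]),
            significant_records(result.eqtls[t2]),
        )
        path = outdir / "direction_concordance.tsv"
        concordance_frame(conc).to_csv(path, sep="\t", index=False)
        outputs["concordance"] = path

        gmt_path = outdir / "inputs" / "gene_sets.gmt"
        if gmt_path.exists() and len(result.shared_genes):
            terms = iof.read_gmt(gmt_path)
            background = sorted({r.gene_id for recs in result.eqtls.values()
                                 for r in recs})
            query = sorted(set(result.shared_genes["gene_id"]) & set(background))
            enr = enrich_genesets(query, terms, background)
            path = outdir / "enrichment.tsv"
            enrichment_frame(enr).to_csv(path, sep="\t", index=False)
            outputs["enrichment"] = path
        return outputs

    _stage("report", _report)

    manifest.to_json(outdir / "manifest.json")
    return result
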