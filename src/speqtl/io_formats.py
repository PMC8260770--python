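"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open.  VCF and GFF3 files are
read and written 1-based (their standards); BED/BEDPE are 0-based half-open;
the SNP/GWAS TSV dialects used here carry an explicit ``pos_1based`` column.
Gzip-compressed inputs are handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("speqtl.io")

SNP_TABLE_COLUMNS = ["rsid", "chrom", "pos_1based", "ref", "alt"]
GWAS_TABLE_COLUMNS = [
    "rsid", "chrom", "pos_1based", "ref", "alt", "beta", "se", "p", "n",
    "trait_type", "locus_id",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """A trait-associated SNP; ``pos`` is 0-based."""

    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    traits: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos < 0:
            raise ValueError(f"{self.rsid}: pos must be >= 0, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with a strand-aware TSS; interval is 0-based half-open."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ContactPair:
    """An unordered Hi-C fragment-fragment contact within one library.

    ``frag_a <= frag_b`` is enforced so that (a, b) and (b, a) compare equal.
    """

    library_id: str
    frag_a: int
    frag_b: int
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("contact count must be >= 1")
        if self.frag_a > self.frag_b:
            a, b = self.frag_b, self.frag_a
            object.__setattr__(self, "frag_a", a)
            object.__setattr__(self, "frag_b", b)

    @property
    def key(self):
        return (min(self.frag_a, self.frag_b), max(self.frag_a, self.frag_b))


@dataclass(frozen=True)
class GwasSummaryRow:
    """One SNP of a GWAS summary-statistics track; ``pos`` is 0-based."""

    rsid: str
    chrom: str
    pos: int
    beta: float
    se: float
    p: float
    n: int
    trait_type: str = "quantitative"
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.rsid}: p must be in (0, 1]")
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"{self.rsid}: unknown trait_type {self.trait_type}")
        _check_z_p_consistency(self.rsid, self.beta, self.se, self.p)


def _check_z_p_consistency(rsid: str, beta: float, se: float, p: float,
                           rel_tol: float = 0.10) -> None:
    """|beta/se| must match the two-sided normal quantile of p to ~10%.

    Skipped for very small z (p near 1), where relative tolerance is
    meaningless.
    """
    from scipy.stats import norm

    z_obs = abs(beta / se)
    z_p = float(norm.isf(p / 2.0))
    if z_p < 0.5:
        return
    if abs(z_obs - z_p) > rel_tol * z_p:
        raise ValueError(
            f"{rsid}: |beta/se|={z_obs:.4g} inconsistent with p={p:.3g} "
            f"(expected z≈{z_p:.4g})"
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {chrom: uppercase sequence} dict."""
    genome: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if not name:
                raise ParseError(f"{path}: FASTA record with empty header")
            if name in genome:
                raise ParseError(f"{path}: duplicate FASTA header '{name}'")
            seq = str(record.seq).upper()
            if not seq:
                raise ParseError(f"{path}: chromosome '{name}' has empty sequence")
            genome[name] = seq
    if not genome:
        raise ParseError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: dict, path, width: int = 80) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(path, trait: str) -> list:
    """Read a trait SNP TSV (1-based positions) into SnpRecords (0-based).

    Duplicate rsIDs within the file are collapsed to the first occurrence
    with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SNP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records: list[SnpRecord] = []
    seen: set[str] = set()
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos1 = int(row.pos_1based)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path} row {i}: non-integer position {row.pos_1based!r}"
            ) from None
        if pos1 < 1:
            raise ParseError(f"{path} row {i}: 1-based position must be >= 1")
        if row.rsid in seen:
            n_dup += 1
            continue
        seen.add(row.rsid)
        records.append(SnpRecord(
            rsid=row.rsid, chrom=row.chrom, pos=pos1 - 1,
            ref=row.ref, alt=row.alt, traits=frozenset({trait}),
        ))
    if n_dup:
        logger.warning("%s: collapsed %d duplicate rsID rows", path, n_dup)
    return records


def write_snp_table(snps: Iterable[SnpRecord], path) -> None:
    df = pd.DataFrame(
        [(s.rsid, s.chrom, s.pos + 1, s.ref, s.alt) for s in snps],
        columns=SNP_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff_genes(path) -> list:
    """Read ``gene`` features from a GFF3 file (1-based inclusive → 0-based)."""
    records: list[GeneRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path} line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = parts
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr.get("ID") or attr.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path} line {lineno}: gene without ID attribute")
            records.append(GeneRecord(
                gene_id=gene_id,
                name=attr.get("Name", gene_id),
                chrom=chrom,
                start=int(start1) - 1,
                end=int(end1),
                strand=strand,
            ))
    return records


def write_gff_genes(genes: Iterable[GeneRecord], path) -> None:
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.name}"
            out.write("\t".join([
                g.chrom, "speqtl", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# BEDPE contacts
# ---------------------------------------------------------------------------

def read_contacts_bedpe(path, fragment_map) -> list:
    """Read BEDPE contact rows and reduce them to restriction-fragment pairs.

    Expected columns (tab-separated, no header): chrom1, start1, end1,
    chrom2, start2, end2, library_id, [count].  Each interval is assigned to
    the fragment containing its midpoint.  Self-pairs (both ends in one
    fragment) are dropped; intervals on unknown chromosomes or outside the
    genome are skipped with a logged tally.  Pairs are canonicalized
    (smaller fragment id first) and counts summed per (library, pair).
    """
    counts: dict[tuple, int] = {}
    n_skipped = 0
    n_self = 0
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path} line {lineno}: expected >= 7 BEDPE columns")
            c1, s1, e1, c2, s2, e2, lib = parts[:7]
            count = int(parts[7]) if len(parts) > 7 else 1
            try:
                fa = fragment_map.fragment_at(c1, (int(s1) + int(e1)) // 2)
                fb = fragment_map.fragment_at(c2, (int(s2) + int(e2)) // 2)
            except KeyError:
                n_skipped += 1
                continue
            if fa == fb:
                n_self += 1
                continue
            key = (lib, min(fa, fb), max(fa, fb))
            counts[key] = counts.get(key, 0) + count
    if n_skipped:
        logger.warning("%s: skipped %d rows outside the genome", path, n_skipped)
    if n_self:
        logger.info("%s: dropped %d self-pairs", path, n_self)
    return [
        ContactPair(library_id=lib, frag_a=fa, frag_b=fb, count=c)
        for (lib, fa, fb), c in sorted(counts.items())
    ]


def write_contacts_bedpe(contacts: Iterable[ContactPair], fragment_map, path) -> None:
    """Write fragment-pair contacts back to BEDPE (fragment intervals)."""
    with _open_text(path, "wt") as out:
        for c in sorted(contacts, key=lambda c: (c.library_id, c.frag_a, c.frag_b)):
            ca, sa, ea = fragment_map.fragment_interval(c.frag_a)
            cb, sb, eb = fragment_map.fragment_interval(c.frag_b)
            out.write("\t".join(map(str, [
                ca, sa, ea, cb, sb, eb, c.library_id, c.count,
            ])) + "\n")


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path) -> pd.DataFrame:
    """Read a VCF into an additive-dosage DataFrame (rsID x sample, {0,1,2}).

    Only the GT field is used; only the first ALT allele is counted.
    Missing genotypes become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rsids, rows = [], []
    for variant in vcf:
        rsids.append(variant.ID)
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = variant.gt_types.astype(float)
        dosage = np.where(gt == 3, 2.0, gt)
        dosage[gt == 2] = np.nan
        rows.append(dosage)
    vcf.close()
    return pd.DataFrame(rows, index=rsids, columns=samples)


def write_vcf_genotypes(dosages: pd.DataFrame, snps: Iterable[SnpRecord], path) -> None:
    """Write an additive dosage matrix as a minimal VCF 4.2 with GT fields.

    Dosage 0/1/2 becomes 0/0, 0/1, 1/1; NaN becomes ./. .  Rows are written
    sorted by (chrom, pos) as the VCF standard requires.
    """
    by_id = {s.rsid: s for s in snps}
    order = sorted(
        (r for r in dosages.index if r in by_id),
        key=lambda r: (by_id[r].chrom, by_id[r].pos),
    )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with _open_text(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(dosages.columns) + "\n")
        for rsid in order:
            s = by_id[rsid]
            calls = [
                "./." if math.isnan(d) else gt_map[int(d)]
                for d in dosages.loc[rsid]
            ]
            out.write("\t".join([
                s.chrom, str(s.pos + 1), rsid, s.ref, s.alt, ".", "PASS", ".",
                "GT", *calls,
            ]) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT file into {term_id: set of gene ids}."""
    terms: dict[str, set] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path} line {lineno}: GMT rows need >= 3 columns")
            term = parts[0]
            if term in terms:
                raise ParseError(f"{path} line {lineno}: duplicate term '{term}'")
            terms[term] = {g for g in parts[2:] if g}
    return terms


def write_gmt(terms: dict, path) -> None:
    with _open_text(path, "wt") as out:
        for term, genes in terms.items():
            out.write("\t".join([term, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# GWAS summary tables
# ---------------------------------------------------------------------------

def read_gwas_summary(path) -> pd.DataFrame:
    """Read a GWAS summary TSV into a 0-based DataFrame, validating each row."""
    df = pd.read_csv(path, sep="\t")
    required = [c for c in GWAS_TABLE_COLUMNS if c not in ("locus_id", "ref", "alt")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for row in df.itertuples(index=False):
        GwasSummaryRow(
            rsid=row.rsid, chrom=row.chrom, pos=int(row.pos_1based) - 1,
            beta=float(row.beta), se=float(row.se), p=float(row.p),
            n=int(row.n), trait_type=row.trait_type,
            ref=getattr(row, "ref", "A"), alt=getattr(row, "alt", "G"),
        )
    out = df.copy()
    out["pos"] = out["pos_1based"].astype(int) - 1
    return out.drop(columns=["pos_1based"])


def write_gwas_summary(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["pos_1based"] = out["pos"].astype(int) + 1
    cols = [c for c in GWAS_TABLE_COLUMNS if c in out.columns or c == "pos_1based"]
    out[cols].to_csv(path, sep="\t", index=False)


def gwas_rows_to_frame(rows: Iterable[GwasSummaryRow], locus_id: str = "") -> pd.DataFrame:
    df = pd.DataFrame([{
        "rsid": r.rsid, "chrom": r.chrom, "pos": r.pos, "ref": r.ref,
        "alt": r.alt, "beta": r.beta, "se": r.se, "p": r.p, "n": r.n,
        "trait_type": r.trait_type,
    } for r in rows])
    if locus_id:
        df["locus_id"] = locus_id
    return df
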