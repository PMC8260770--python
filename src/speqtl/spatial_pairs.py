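"""Spatial SNP-gene candidate pairing through Hi-C fragment contacts.

A SNP and a gene form a spatial pair when the restriction fragment carrying
the SNP is in physical contact (in at least one Hi-C library) with the
fragment carrying the gene anchor.  SNP-gene pairs that share a single
fragment are also emitted, flagged ``same_fragment``, since contacts within
one fragment are unobservable by construction.  Contacts are treated as
binary evidence: one supporting read pair is enough, and no
contact-frequency threshold is applied.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("speqtl.spatial")


@dataclass
class SpatialPair:
    """A SNP-gene candidate supported by Hi-C contact or fragment identity."""

    rsid: str
    gene_id: str
    supporting_libraries: frozenset = field(default_factory=frozenset)
    n_contacts: int = 0
    same_fragment: bool = False

    def __post_init__(self):
        if not self.supporting_libraries and not self.same_fragment:
            raise ValueError(
                f"{self.rsid}-{self.gene_id}: pair needs a contact library "
                "or the same_fragment flag"
            )


def _gene_fragments(gene, fragment_map, gene_anchor: str) -> list:
    if gene_anchor == "tss":
        return [fragment_map.fragment_at(gene.chrom, gene.tss)]
    if gene_anchor == "any-overlap":
        return fragment_map.overlapping_fragments(gene.chrom, gene.start, gene.end)
    raise ValueError(f"unknown gene_anchor {gene_anchor!r}")


def find_spatial_pairs(snps, genes, fragment_map, contacts,
                       gene_anchor: str = "tss") -> list:
    """Intersect SNP fragments with gene fragments through contact pairs.

    Returns one :class:`SpatialPair` per (rsid, gene_id), deduplicated
    across libraries with library provenance retained and contact counts
    summed.  Output is sorted by (rsid, gene_id) and invariant to the order
    of the contact list.  SNPs or genes on chromosomes absent from the
    fragment map are skipped with a logged tally.
    """
    snps_by_frag: dict[int, list] = defaultdict(list)
    n_skipped = 0
    for snp in snps:
        try:
            snps_by_frag[fragment_map.fragment_at(snp.chrom, snp.pos)].append(snp.rsid)
        except (KeyError, IndexError):
            n_skipped += 1
    genes_by_frag: dict[int, list] = defaultdict(list)
    for gene in genes:
        try:
            for fid in _gene_fragments(gene, fragment_map, gene_anchor):
                genes_by_frag[fid].append(gene.gene_id)
        except (KeyError, IndexError):
            n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d SNPs/genes outside the fragment map", n_skipped)

    libs: dict[tuple, set] = defaultdict(set)
    counts: dict[tuple, int] = defaultdict(int)
    same_frag: set[tuple] = set()

    for contact in contacts:
        fa, fb = contact.frag_a, contact.frag_b
        for f_snp, f_gene in ((fa, fb), (fb, fa)):
            for rsid in snps_by_frag.get(f_snp, ()):
                for gene_id in genes_by_frag.get(f_gene, ()):
                    key = (rsid, gene_id)
                    libs[key].add(contact.library_id)
                    counts[key] += contact.count

    for fid, rsids in snps_by_frag.items():
        for gene_id in genes_by_frag.get(fid, ()):
            for rsid in rsids:
                same_frag.add((rsid, gene_id))

    pairs = [
        SpatialPair(
            rsid=rsid, gene_id=gene_id,
            supporting_libraries=frozenset(libs.get((rsid, gene_id), ())),
            n_contacts=counts.get((rsid, gene_id), 0),
            same_fragment=(rsid, gene_id) in same_frag,
        )
        for (rsid, gene_id) in sorted(set(libs) | same_frag)
    ]
    return pairs


def pairs_from_frame(df: pd.DataFrame) -> list:
    """Inverse of :func:`pairs_to_frame` (TSV round-trip)."""
    out = []
    for row in df.itertuples(index=False):
        libs = str(row.libraries) if not pd.isna(row.libraries) else ""
        out.append(SpatialPair(
            rsid=row.rsid, gene_id=row.gene_id,
            supporting_libraries=frozenset(l for l in libs.split(",") if l),
            n_contacts=int(row.n_contacts),
            same_fragment=bool(row.same_fragment),
        ))
    return out


def pair_statistics(pairs) -> dict:
    """Counting summary of a spatial-pair list.

    ``per_snp_histogram`` maps pairs-per-SNP to the number of SNPs with that
    many pairs.  Multi-library pairs count once per supporting library in
    ``pairs_per_library``, so those counts can sum to more than the number
    of pairs.
    """
    per_snp = Counter(p.rsid for p in pairs)
    per_gene = Counter(p.gene_id for p in pairs)
    per_library: Counter = Counter()
    for p in pairs:
        per_library.update(p.supporting_libraries)
    return {
        "n_pairs": len(pairs),
        "n_snps": len(per_snp),
        "n_genes": len(per_gene),
        "pairs_per_snp": dict(per_snp),
        "pairs_per_gene": dict(per_gene),
        "pairs_per_library": dict(per_library),
        "per_snp_histogram": dict(Counter(per_snp.values())),
        "n_same_fragment": sum(p.same_fragment for p in pairs),
    }


def pairs_to_frame(pairs) -> pd.DataFrame:
    """TSV-ready table: rsid, gene_id, libraries, n_contacts, same_fragment."""
    return pd.DataFrame([{
        "rsid": p.rsid,
        "gene_id": p.gene_id,
        "libraries": ",".join(sorted(p.supporting_libraries)),
        "n_contacts": p.n_contacts,
        "same_fragment": p.same_fragment,
    } for p in pairs], columns=[
        "rsid", "gene_id", "libraries", "n_contacts", "same_fragment",
    ])
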