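"""In-silico restriction digestion and fragment assignment.

The genome is cut at every exact forward-strand occurrence of the enzyme
motif (offset by ``cut_offset`` bases into the motif, MboI-style ^GATC by
default).  The fragments between consecutive cuts tile each chromosome
exactly; they are the spatial unit for all Hi-C contact logic.  Palindromic
motifs — which the common Hi-C enzymes use — make forward-strand matching
lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("speqtl.fragments")

_VALID_BASES = set("ACGT")


@dataclass
class FragmentMap:
    """Restriction fragments tiling a genome.

    Fragment ids are consecutive integers assigned in (chrom, start) order,
    with chromosomes sorted lexicographically so the map is independent of
    genome input order.
    """

    enzyme_motif: str
    cut_offset: int
    chroms: list = field(default_factory=list)
    _starts: dict = field(default_factory=dict)   # chrom -> np.ndarray
    _ends: dict = field(default_factory=dict)
    _id_offset: dict = field(default_factory=dict)
    _chrom_of: list = field(default_factory=list)  # fragment id -> chrom

    @property
    def n_fragments(self) -> int:
        return len(self._chrom_of)

    def chrom_length(self, chrom: str) -> int:
        return int(self._ends[chrom][-1])

    def fragments(self, chrom: str):
        """Ordered (start, end, fragment_id) triples for one chromosome."""
        off = self._id_offset[chrom]
        return [
            (int(s), int(e), off + i)
            for i, (s, e) in enumerate(zip(self._starts[chrom], self._ends[chrom]))
        ]

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Id of the unique fragment with start <= pos < end."""
        if chrom not in self._starts:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = self.chrom_length(chrom)
        if pos < 0 or pos >= length:
            raise IndexError(
                f"position {pos} outside chromosome {chrom} [0, {length})"
            )
        idx = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        return self._id_offset[chrom] + idx

    def fragment_interval(self, fragment_id: int):
        """(chrom, start, end) of a fragment id."""
        chrom = self._chrom_of[fragment_id]
        i = fragment_id - self._id_offset[chrom]
        return chrom, int(self._starts[chrom][i]), int(self._ends[chrom][i])

    def overlapping_fragments(self, chrom: str, start: int, end: int) -> list:
        """Ids of all fragments intersecting [start, end)."""
        if start >= end:
            raise ValueError("empty interval")
        length = self.chrom_length(chrom)
        start = max(start, 0)
        end = min(end, length)
        if start >= length or end <= 0:
            return []
        first = self.fragment_at(chrom, start)
        last = self.fragment_at(chrom, end - 1)
        return list(range(first, last + 1))

    def to_bed(self, path) -> None:
        """Serialize as BED with the fragment id in the name column."""
        with open(path, "w") as out:
            for chrom in self.chroms:
                for start, end, fid in self.fragments(chrom):
                    out.write(f"{chrom}\t{start}\t{end}\tF{fid}\n")

    def validate(self) -> None:
        """Assert the exact-tiling invariant."""
        for chrom in self.chroms:
            starts, ends = self._starts[chrom], self._ends[chrom]
            assert starts[0] == 0, f"{chrom}: first fragment must start at 0"
            assert np.all(starts[1:] == ends[:-1]), f"{chrom}: gap or overlap"
            assert np.all(ends > starts), f"{chrom}: empty fragment"


def _find_cut_positions(seq: str, motif: str, cut_offset: int) -> list:
    """All cut positions from exact (possibly overlapping) motif matches."""
    cuts = []
    i = seq.find(motif)
    while i != -1:
        cuts.append(i + cut_offset)
        i = seq.find(motif, i + 1)  # step 1 so overlapping matches count
    return cuts


def digest(genome: dict, motif: str = "GATC", cut_offset: int = 0) -> FragmentMap:
    """Digest a genome ({chrom: sequence}) into a :class:`FragmentMap`.

    Cut positions are ``match start + cut_offset`` for every exact match of
    ``motif`` on the forward strand; fragments are the intervals between
    consecutive cuts and the chromosome ends.  A chromosome with no match
    yields a single fragment covering it.
    """
    if len(motif) < 1:
        raise ValueError("motif must have length >= 1")
    if not set(motif) <= _VALID_BASES:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not (0 <= cut_offset <= len(motif)):
        raise ValueError("cut_offset must lie within the motif")

    fmap = FragmentMap(enzyme_motif=motif, cut_offset=cut_offset)
    next_id = 0
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        length = len(seq)
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} is empty")
        cuts = sorted({c for c in _find_cut_positions(seq, motif, cut_offset)
                       if 0 < c < length})
        bounds = np.array([0, *cuts, length], dtype=np.int64)
        fmap.chroms.append(chrom)
        fmap._starts[chrom] = bounds[:-1]
        fmap._ends[chrom] = bounds[1:]
        fmap._id_offset[chrom] = next_id
        n = len(bounds) - 1
        fmap._chrom_of.extend([chrom] * n)
        next_id += n
    fmap.validate()
    return fmap


def assign_to_fragment(chrom: str, pos: int, fragment_map: FragmentMap) -> int:
    """Fragment id containing a point position (SNP pos or gene TSS)."""
    return fragment_map.fragment_at(chrom, pos)
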