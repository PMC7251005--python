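"""Flank mapping and the mapping-quality filter.

The internal mapper is seed-and-verify: every k-mer of the reference is
indexed; a flank's non-overlapping seeds propose candidate placements on
both strands, each verified by Hamming comparison with an early exit.
With seed length ``k <= len(flank) // (max_mismatch + 1)`` the flank has
at least ``max_mismatch + 1`` disjoint seeds, so any placement within
the mismatch budget leaves one seed error-free — the mapper is then
exactly equivalent to a brute-force Hamming scan of the genome
(pigeonhole), including tie counting.

Mapping quality is binary by contract: a unique best placement gets
MAPQ 60, any tie gets MAPQ 0. Externally aligned reads enter through the
SAM adapter, which re-derives the junction coordinate and passes the
aligner's own MAPQ through; the screen's filter keeps MAPQ strictly
greater than 30.

Junction convention: ``pos`` is always the 0-based start of the TTAA
tetramer on the forward reference strand. A '+' cassette reads away from
the motif's right edge (junction = placement start − 4); a '−' cassette
reads away from its left edge (junction = placement end), so both reads
of one event collapse onto the same key.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import SyntheticGenome, revcomp

__all__ = [
    "AlignedFlank",
    "SeedIndex",
    "build_index",
    "map_flank",
    "map_flanks",
    "filter_mapq",
    "alignments_from_sam",
    "brute_force_map",
]

MOTIF_LEN = 4


@dataclass(frozen=True, slots=True)
class AlignedFlank:
    read_id: str
    sample_id: str | None
    chrom: str
    pos: int  # 0-based start of the target tetramer, forward strand
    strand: str  # cassette orientation
    mapq: int
    n_hits: int
    mismatches: int


class SeedIndex:
    """Exact k-mer index of the forward strand of a genome."""

    def __init__(self, genome: SyntheticGenome, k: int):
        if k < 8:
            raise ValueError("k must be >= 8 (shorter seeds are collision-dominated)")
        if genome.genome_size == 0 or not genome.chromosomes:
            raise ValueError("empty genome")
        if all(len(s) < k for _, s in genome.chromosomes):
            raise ValueError("k exceeds every chromosome length")
        self.k = k
        self.names = genome.names
        self.seqs = [s for _, s in genome.chromosomes]
        index: dict[str, list[tuple[int, int]]] = {}
        for ci, seq in enumerate(self.seqs):
            for p in range(len(seq) - k + 1):
                index.setdefault(seq[p : p + k], []).append((ci, p))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        """Forward-strand positions of ``kmer`` as (chrom_index, pos)."""
        return self._index.get(kmer, ())


def build_index(genome: SyntheticGenome, k: int = 13) -> SeedIndex:
    return SeedIndex(genome, k)


def _verify(seq: str, start: int, query: str, limit: int) -> int:
    s = seq[start : start + len(query)]
    if s == query:
        return 0
    d = 0
    for a, b in zip(s, query):
        if a != b:
            d += 1
            if d > limit:
                return d
    return d


def _junction(ci: int, start: int, strand: str, L: int, index: SeedIndex):
    """Junction tetramer start from a flank placement, or None if off-end."""
    if strand == "+":
        pos = start - MOTIF_LEN
        if pos < 0:
            return None
    else:
        pos = start + L
        if pos + MOTIF_LEN > len(index.seqs[ci]):
            return None
    return pos


def map_flank(
    flank: str,
    index: SeedIndex,
    max_mismatch: int = 2,
    read_id: str = "",
    sample_id: str | None = None,
) -> AlignedFlank | None:
    """Map one flank; returns None when no placement is within budget.

    Ties (n_hits > 1) are reported with mapq 0 at the lexicographically
    first placement — never resolved by arbitrary choice; the downstream
    MAPQ filter removes them.
    """
    L = len(flank)
    k = index.k
    if L < k:
        return None
    queries = ((flank, "+"), (revcomp(flank), "-"))
    offsets = list(range(0, L - k + 1, k))
    if offsets[-1] != L - k:
        offsets.append(L - k)

    candidates: set[tuple[int, int, str]] = set()
    for query, strand in queries:
        for off in offsets:
            for ci, p in index.lookup(query[off : off + k]):
                start = p - off
                if 0 <= start <= len(index.seqs[ci]) - L:
                    candidates.add((ci, start, strand))
    if not candidates:
        return None

    best = max_mismatch + 1
    hits: list[tuple[int, int, str]] = []
    qmap = {"+": flank, "-": revcomp(flank)}
    for ci, start, strand in candidates:
        d = _verify(index.seqs[ci], start, qmap[strand], best)
        if d < best:
            best = d
            hits = [(ci, start, strand)]
        elif d == best:
            hits.append((ci, start, strand))
    if best > max_mismatch:
        return None

    hits.sort()
    junctions = []
    for ci, start, strand in hits:
        pos = _junction(ci, start, strand, L, index)
        if pos is not None:
            junctions.append((ci, pos, strand))
    if not junctions:
        return None
    n = len(junctions)
    ci, pos, strand = junctions[0]
    return AlignedFlank(
        read_id=read_id,
        sample_id=sample_id,
        chrom=index.names[ci],
        pos=pos,
        strand=strand,
        mapq=60 if n == 1 else 0,
        n_hits=n,
        mismatches=best,
    )


def map_flanks(
    reads: Iterable[tuple[str, str | None, str]],
    index: SeedIndex,
    max_mismatch: int = 2,
) -> tuple[pd.DataFrame, int]:
    """Map (read_id, sample_id, flank) triples to a tidy frame.

    Returns (alignments frame, unmapped count).
    """
    rows = []
    unmapped = 0
    for read_id, sample_id, flank in reads:
        a = map_flank(flank, index, max_mismatch, read_id, sample_id)
        if a is None:
            unmapped += 1
        else:
            rows.append((a.read_id, a.sample_id, a.chrom, a.pos, a.strand,
                         a.mapq, a.n_hits, a.mismatches))
    df = pd.DataFrame(
        rows,
        columns=["read_id", "sample_id", "chrom", "pos", "strand",
                 "mapq", "n_hits", "mismatches"],
    )
    return df, unmapped


def filter_mapq(alignments, threshold: int = 30):
    """Keep alignments with MAPQ strictly greater than ``threshold``."""
    if isinstance(alignments, pd.DataFrame):
        return alignments[alignments["mapq"] > threshold].reset_index(drop=True)
    return [a for a in alignments if a.mapq > threshold]


def brute_force_map(
    flank: str, genome: SyntheticGenome, max_mismatch: int = 2
) -> AlignedFlank | None:
    """Exhaustive Hamming scan over every placement on both strands.

    Independent reference for the seed-and-verify mapper; vectorised so
    genomes up to ~100 kb are practical, but still O(genome x flank).
    """
    L = len(flank)
    best = max_mismatch + 1
    hits: list[tuple[int, int, str]] = []
    queries = {"+": np.frombuffer(flank.encode(), dtype=np.uint8),
               "-": np.frombuffer(revcomp(flank).encode(), dtype=np.uint8)}
    for ci, (_, seq) in enumerate(genome.chromosomes):
        if len(seq) < L:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, q in queries.items():
            mm = (windows != q).sum(axis=1)
            for start in np.nonzero(mm <= max_mismatch)[0]:
                d = int(mm[start])
                if d < best:
                    best = d
                    hits = [(ci, int(start), strand)]
                elif d == best:
                    hits.append((ci, int(start), strand))
    if best > max_mismatch or not hits:
        return None
    hits.sort()
    names = genome.names
    seqs = [s for _, s in genome.chromosomes]

    junctions = []
    for ci, start, strand in hits:
        if strand == "+":
            pos = start - MOTIF_LEN
            if pos < 0:
                continue
        else:
            pos = start + L
            if pos + MOTIF_LEN > len(seqs[ci]):
                continue
        junctions.append((ci, pos, strand))
    if not junctions:
        return None
    ci, pos, strand = junctions[0]
    return AlignedFlank("", None, names[ci], pos, strand,
                        60 if len(junctions) == 1 else 0, len(junctions), best)


def alignments_from_sam(
    path: str | Path, sample_id: str | None = None
) -> list[AlignedFlank]:
    """Adapt externally aligned flanks (SAM/BAM) to junction calls.

    The junction is re-derived from the alignment: on '+' it sits
    MOTIF_LEN bases left of where the full flank would start (soft-clips
    at the flank's 5' end shift the inferred start); on '−' it sits at
    the position just right of the full flank's end. The aligner's MAPQ
    passes through untouched; n_hits comes from the NH tag when present.
    """
    import pysam

    out: list[AlignedFlank] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as sam:
        lengths = {r: l for r, l in zip(sam.references, sam.lengths)}
        for a in sam:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.is_reverse:
                clip5 = a.query_length - a.query_alignment_end
                pos = a.reference_end + clip5
                strand = "-"
                if pos + MOTIF_LEN > lengths[a.reference_name]:
                    continue
            else:
                clip5 = a.query_alignment_start
                pos = a.reference_start - clip5 - MOTIF_LEN
                strand = "+"
                if pos < 0:
                    continue
            n_hits = a.get_tag("NH") if a.has_tag("NH") else 1
            nm = a.get_tag("NM") if a.has_tag("NM") else 0
            out.append(
                AlignedFlank(a.query_name, sample_id, a.reference_name, pos,
                             strand, a.mapping_quality, int(n_hits), int(nm))
            )
    return out
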