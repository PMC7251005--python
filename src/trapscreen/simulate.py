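"""Synthetic data for gene-trap screen informatics.

Generates a small random reference genome, a non-overlapping gene
annotation, clonal PiggyBac insertion libraries, and barcoded
splinkerette-style FASTQ reads with a ground-truth table, so every
downstream stage (demultiplexing, mapping, insertion calling, screen
statistics) can be tested against known truth.

The generative model mirrors the structure of a one-insertion-per-cell
gene-trap screen in haploid cells:

* each clone carries exactly one *primary* insertion at a TTAA
  tetranucleotide (the PiggyBac target motif), plus a small geometric
  number of *secondary* insertions modelling incomplete self-inactivation
  of the transposase;
* insertion sites inside transcription units are favoured by a
  configurable weight (``tu_bias``), reflecting the observed integration
  preference of the transposon within genes;
* every read has a fixed layout: clone/library barcode, a constant
  transposon terminal-repeat tag, the TTAA junction, then the genomic
  flank downstream of the junction on the cassette strand, with i.i.d.
  substitution errors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticGenome",
    "GeneModel",
    "InsertionEvent",
    "ClonePopulation",
    "ReadSimConfig",
    "generate_genome",
    "generate_annotation",
    "generate_barcodes",
    "simulate_library",
    "simulate_bulk_events",
    "simulate_splinkerette_reads",
    "find_motif",
    "revcomp",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# uint8 lookup tables for vectorised error injection
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def find_motif(seq: str, motif: str = "TTAA") -> np.ndarray:
    """All 0-based start positions of ``motif`` in ``seq`` (overlap-aware)."""
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class SyntheticGenome:
    """A toy reference genome: ordered (name, sequence) chromosomes."""

    chromosomes: tuple[tuple[str, str], ...]

    @property
    def genome_size(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def sequence(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)

    def motif_sites(self, motif: str = "TTAA") -> dict[str, np.ndarray]:
        """Per-chromosome start positions of the target motif."""
        return {n: find_motif(s, motif) for n, s in self.chromosomes}

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SyntheticGenome":
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        with open(path) as fh:
            chroms = tuple(
                (title.split()[0], seq.upper()) for title, seq in SimpleFastaParser(fh)
            )
        if not chroms:
            raise ValueError(f"no sequences in {path}")
        return cls(chroms)


def generate_genome(
    n_chrom: int,
    chrom_length: int,
    gc: float = 0.5,
    seed: int = 0,
    motif: str = "TTAA",
    max_attempts: int = 20,
) -> SyntheticGenome:
    """Random genome of ``n_chrom`` chromosomes of ``chrom_length`` bp.

    Bases are i.i.d. with the given GC fraction. Each chromosome is
    guaranteed to contain at least one occurrence of the target motif;
    a chromosome without one is redrawn up to ``max_attempts`` times.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chroms = []
    for i in range(n_chrom):
        for _ in range(max_attempts):
            idx = rng.choice(4, size=chrom_length, p=p)
            seq = _DECODE[idx].tobytes().decode()
            if motif in seq:
                break
        else:
            raise RuntimeError(
                f"no {motif} sites obtained in {max_attempts} draws of a "
                f"{chrom_length} bp chromosome"
            )
        chroms.append((f"chr{i + 1}", seq))
    return SyntheticGenome(tuple(chroms))


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class GeneModel:
    """A gene: half-open 0-based span with sorted non-overlapping exons.

    The first exon starts at ``start`` and the last ends at ``end`` so
    that exon + intron lengths sum exactly to the span length.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ValueError(f"bad exon structure in {self.gene_id}")
            prev = e
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise ValueError(f"exons must touch both span ends in {self.gene_id}")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def length(self) -> int:
        return self.end - self.start


def generate_annotation(
    genome: SyntheticGenome,
    n_genes: int,
    exons_per_gene: int = 3,
    seed: int = 0,
    gene_length: tuple[int, int] = (1000, 3000),
    max_attempts: int = 100,
) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping genes on the genome.

    Genes are allocated to chromosomes proportionally to length, then
    laid out with a stars-and-bars draw of the inter-gene gaps, so
    placement always succeeds when the total gene length fits. Exon
    boundaries are distinct interior cut points, giving ``exons_per_gene``
    exons that touch both span ends; exon + intron + intergenic lengths
    partition the genome exactly.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if exons_per_gene < 1:
        raise ValueError("exons_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(s) for _, s in genome.chromosomes], dtype=float)
    # largest-remainder allocation proportional to chromosome length
    quota = n_genes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    rem = n_genes - counts.sum()
    if rem > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:rem]] += 1

    genes: list[GeneModel] = []
    gid = 0
    lo, hi = gene_length
    for (name, seq), k in zip(genome.chromosomes, counts):
        if k == 0:
            continue
        clen = len(seq)
        for _ in range(max_attempts):
            glens = rng.integers(lo, hi + 1, size=k)
            if glens.sum() <= clen:
                break
        else:
            raise RuntimeError(
                f"cannot place {k} genes of {lo}-{hi} bp on {name} ({clen} bp)"
            )
        free = clen - int(glens.sum())
        cuts = np.sort(rng.integers(0, free + 1, size=k))  # gap prefix sums
        starts = cuts + np.concatenate(([0], np.cumsum(glens[:-1])))
        for g_start, g_len in zip(starts, glens):
            gid += 1
            g_start = int(g_start)
            g_end = g_start + int(g_len)
            if exons_per_gene == 1:
                exons = ((g_start, g_end),)
            else:
                interior = rng.choice(
                    np.arange(g_start + 1, g_end), size=2 * exons_per_gene - 2,
                    replace=False,
                )
                b = np.sort(interior)
                bounds = [g_start, *b.tolist(), g_end]
                exons = tuple(
                    (bounds[2 * i], bounds[2 * i + 1]) for i in range(exons_per_gene)
                )
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}",
                    chrom=name,
                    strand=str(rng.choice(["+", "-"])),
                    start=g_start,
                    end=g_end,
                    exons=exons,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# clonal libraries


@dataclass(frozen=True)
class InsertionEvent:
    """One cassette insertion at a target-motif site."""

    chrom: str
    pos: int  # 0-based start of the TTAA tetramer on the forward strand
    strand: str  # cassette orientation
    is_primary: bool


@dataclass(frozen=True)
class ClonePopulation:
    """A simulated clone: barcode, cell fraction, and its insertions."""

    clone_id: str
    barcode: str
    abundance: float
    events: tuple[InsertionEvent, ...]

    def __post_init__(self) -> None:
        if sum(e.is_primary for e in self.events) != 1:
            raise ValueError(f"{self.clone_id}: exactly one primary event required")

    @property
    def primary(self) -> InsertionEvent:
        return next(e for e in self.events if e.is_primary)

    @property
    def n_secondary(self) -> int:
        return len(self.events) - 1


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_barcodes(
    n: int,
    length: int = 8,
    min_dist: int = 3,
    seed: int = 0,
    max_attempts: int = 200_000,
) -> list[str]:
    """Greedy random barcode set with pairwise Hamming distance >= min_dist."""
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    attempts = 0
    while len(codes) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not build {n} barcodes of length {length} at "
                f"distance {min_dist} in {max_attempts} draws; "
                "increase barcode length"
            )
        cand = _DECODE[rng.integers(0, 4, size=length)].tobytes().decode()
        if all(_hamming(cand, c) >= min_dist for c in codes):
            codes.append(cand)
    return codes


def _site_census(
    genome: SyntheticGenome,
    annotation: Sequence[GeneModel] | None,
    motif: str,
    end_margin: int,
):
    """Usable motif sites with in-transcription-unit flags.

    Sites within ``end_margin`` bp of either chromosome end are excluded so
    that a read flank never runs off the sequence, whichever strand the
    cassette lands on.
    """
    chrom_idx: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    in_tu: list[np.ndarray] = []
    spans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if annotation:
        for name in genome.names:
            g = sorted(
                [(g.start, g.end) for g in annotation if g.chrom == name]
            )
            spans[name] = (
                np.array([s for s, _ in g], dtype=np.int64),
                np.array([e for _, e in g], dtype=np.int64),
            )
    for ci, (name, seq) in enumerate(genome.chromosomes):
        pos = find_motif(seq, motif)
        pos = pos[(pos >= end_margin) & (pos + len(motif) <= len(seq) - end_margin)]
        if annotation and name in spans and len(spans[name][0]):
            starts, ends = spans[name]
            j = np.searchsorted(starts, pos, side="right") - 1
            flag = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        else:
            flag = np.zeros(len(pos), dtype=bool)
        chrom_idx.append(np.full(len(pos), ci, dtype=np.int64))
        positions.append(pos)
        in_tu.append(flag)
    ci = np.concatenate(chrom_idx)
    pos = np.concatenate(positions)
    tu = np.concatenate(in_tu)
    if len(pos) == 0:
        raise RuntimeError("no usable target-motif sites in the genome")
    return ci, pos, tu


def simulate_library(
    genome: SyntheticGenome,
    annotation: Sequence[GeneModel] | None,
    n_clones: int,
    secondary_rate: float = 0.1,
    tu_bias: float = 5.0,
    seed: int = 0,
    barcode_length: int = 8,
    barcode_min_dist: int = 3,
    motif: str = "TTAA",
    end_margin: int = 100,
    abundance: str = "dirichlet",
) -> list[ClonePopulation]:
    """Simulate a clonal gene-trap library.

    Each clone gets one primary insertion at a motif site drawn with
    weight ``tu_bias`` inside transcription units and 1 outside, a fair-coin
    cassette strand, and ``k`` secondary insertions with
    ``P(k) = (1 - secondary_rate) * secondary_rate**k`` (incomplete
    transposase self-inactivation). Barcodes are unique with pairwise
    Hamming distance >= ``barcode_min_dist``. Abundances are a flat
    Dirichlet draw by default (uneven clone sizes, as after random
    expansion); pass ``abundance='uniform'`` for equal cell fractions.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not 0.0 <= secondary_rate < 1.0:
        raise ValueError("secondary_rate must be in [0, 1)")
    if tu_bias < 1.0:
        raise ValueError("tu_bias must be >= 1")
    rng = np.random.default_rng(seed)
    ci, pos, tu = _site_census(genome, annotation, motif, end_margin)
    w = np.where(tu, tu_bias, 1.0)
    probs = w / w.sum()
    names = genome.names

    barcodes = generate_barcodes(
        n_clones, barcode_length, barcode_min_dist, seed=rng.integers(2**31)
    )
    if abundance == "uniform":
        abundances = np.full(n_clones, 1.0 / n_clones)
    elif abundance == "dirichlet":
        abundances = rng.dirichlet(np.ones(n_clones))
    else:
        raise ValueError("abundance must be 'dirichlet' or 'uniform'")
    if secondary_rate > 0:
        n_sec = rng.geometric(1.0 - secondary_rate, size=n_clones) - 1
    else:
        n_sec = np.zeros(n_clones, dtype=np.int64)

    clones = []
    for i in range(n_clones):
        k = 1 + int(n_sec[i])
        draws = rng.choice(len(pos), size=k, p=probs)
        strands = rng.choice(["+", "-"], size=k)
        events = tuple(
            InsertionEvent(
                chrom=names[ci[d]],
                pos=int(pos[d]),
                strand=str(s),
                is_primary=(j == 0),
            )
            for j, (d, s) in enumerate(zip(draws, strands))
        )
        clones.append(
            ClonePopulation(
                clone_id=f"clone{i + 1:03d}",
                barcode=barcodes[i],
                abundance=float(abundances[i]),
                events=events,
            )
        )
    return clones


def simulate_bulk_events(
    genome: SyntheticGenome,
    annotation: Sequence[GeneModel] | None,
    n_insertions: int,
    tu_bias: float = 1.0,
    seed: int = 0,
    motif: str = "TTAA",
    end_margin: int = 100,
) -> pd.DataFrame:
    """Population-scale insertion events for a bulk coverage assay.

    Models the transposition of a large cell population sequenced in bulk
    under one library barcode: every event is independent, lands on a
    motif site (weighted ``tu_bias`` inside transcription units), and takes
    a fair-coin cassette strand. Returns a frame with columns
    ``chrom, pos, strand, is_primary``.
    """
    if n_insertions < 1:
        raise ValueError("n_insertions must be >= 1")
    rng = np.random.default_rng(seed)
    ci, pos, tu = _site_census(genome, annotation, motif, end_margin)
    w = np.where(tu, tu_bias, 1.0)
    probs = w / w.sum()
    draws = rng.choice(len(pos), size=n_insertions, p=probs)
    strands = rng.choice(np.array(["+", "-"]), size=n_insertions)
    names = np.array(genome.names)
    return pd.DataFrame(
        {
            "chrom": names[ci[draws]],
            "pos": pos[draws],
            "strand": strands,
            "is_primary": True,
        }
    )


# ---------------------------------------------------------------------------
# read synthesis


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of the splinkerette read simulator.

    Read layout: barcode | tr_tag | TTAA | genomic flank, truncated to
    ``read_length``; substitution errors are i.i.d. per base at
    ``error_rate``. Within a clone, the primary event receives relative
    read weight 1 and each secondary event ``secondary_read_weight``
    (default 0.1: with one secondary the primary holds ~91% of the
    clone's reads); ``primary_fraction`` overrides this with a fixed
    primary share.
    """

    n_reads: int
    read_length: int = 64
    error_rate: float = 0.005
    tr_tag: str = "CGTCAGTCGAGC"
    motif: str = "TTAA"
    seed: int = 0
    secondary_read_weight: float = 0.1
    primary_fraction: float | None = None
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.primary_fraction is not None and not 0.0 < self.primary_fraction <= 1.0:
            raise ValueError("primary_fraction must be in (0, 1]")

    def flank_length(self, barcode_length: int) -> int:
        fl = self.read_length - barcode_length - len(self.tr_tag) - len(self.motif)
        if fl < 1:
            raise ValueError(
                "read_length must exceed barcode + tr_tag + motif length"
            )
        return fl


def _event_rows(
    library: Iterable[ClonePopulation], cfg: ReadSimConfig
) -> tuple[list[tuple], np.ndarray]:
    """Flatten (clone, event) pairs with read-allocation weights."""
    rows = []
    weights = []
    for clone in library:
        k = clone.n_secondary
        if cfg.primary_fraction is not None and k > 0:
            wp, ws = cfg.primary_fraction, (1.0 - cfg.primary_fraction) / k
        else:
            wp, ws = 1.0, cfg.secondary_read_weight
        tot = wp + ws * k
        for ev in clone.events:
            w = (wp if ev.is_primary else ws) / tot
            rows.append((clone.clone_id, clone.barcode, ev))
            weights.append(clone.abundance * w)
    w = np.asarray(weights, dtype=float)
    return rows, w / w.sum()


def _flank(genome: SyntheticGenome, ev: InsertionEvent, motif_len: int, L: int) -> str:
    """Genomic flank downstream of the junction on the cassette strand."""
    seq = genome.sequence(ev.chrom)
    if ev.strand == "+":
        s = seq[ev.pos + motif_len : ev.pos + motif_len + L]
    else:
        s = revcomp(seq[max(0, ev.pos - L) : ev.pos])
    if len(s) < L:
        raise ValueError(
            f"flank runs off {ev.chrom} at pos {ev.pos} ({ev.strand}); "
            "exclude end-proximal sites via end_margin"
        )
    return s


def _apply_errors(block: np.ndarray, error_rate: float, rng) -> None:
    """In-place i.i.d. substitutions; an error never reproduces the base."""
    if error_rate <= 0 or block.size == 0:
        return
    mask = rng.random(block.shape) < error_rate
    idx = np.nonzero(mask)
    if len(idx[0]) == 0:
        return
    orig = _CODE[block[idx]]
    shift = rng.integers(1, 4, size=len(idx[0]))
    block[idx] = _DECODE[(orig + shift) % 4]


def simulate_splinkerette_reads(
    library: Sequence[ClonePopulation] | pd.DataFrame,
    genome: SyntheticGenome,
    cfg: ReadSimConfig,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
    bulk_barcode: str = "AACCGGTT",
    bulk_sample_id: str = "bulk",
    chunk_size: int = 200_000,
) -> pd.DataFrame:
    """Write a splinkerette FASTQ and its ground-truth table.

    ``library`` is either a list of :class:`ClonePopulation` (reads are
    allocated by clone abundance and primary/secondary weight) or a bulk
    event frame from :func:`simulate_bulk_events` (one read per event,
    all under ``bulk_barcode``). Deterministic for a fixed ``cfg.seed``:
    two runs produce byte-identical FASTQ. Returns the ground-truth
    frame (read_id, sample_id, chrom, pos, strand, is_primary) with the
    per-read allocation also written to ``truth_path`` when given.
    """
    rng = np.random.default_rng(cfg.seed)

    if isinstance(library, pd.DataFrame):
        rows = [
            (bulk_sample_id, bulk_barcode,
             InsertionEvent(r.chrom, int(r.pos), r.strand, bool(r.is_primary)))
            for r in library.itertuples(index=False)
        ]
        if len(rows) != cfg.n_reads:
            raise ValueError("bulk mode expects one read per event (n_reads == len(events))")
        counts = np.ones(len(rows), dtype=np.int64)
        barcode_length = len(bulk_barcode)
        manifest = pd.DataFrame({"sample_id": [bulk_sample_id], "barcode": [bulk_barcode]})
    else:
        if not library:
            raise ValueError("empty library")
        rows_w, probs = _event_rows(library, cfg)
        rows = rows_w
        counts = rng.multinomial(cfg.n_reads, probs)
        barcode_length = len(library[0].barcode)
        if any(len(c.barcode) != barcode_length for c in library):
            raise ValueError("all barcodes must share one length")
        manifest = pd.DataFrame(
            {"sample_id": [c.clone_id for c in library],
             "barcode": [c.barcode for c in library]}
        )

    L = cfg.flank_length(barcode_length)
    qual = cfg.quality_char * cfg.read_length

    # one template per (sample, event) row; reads are error-mutated copies
    templates = np.empty((len(rows), cfg.read_length), dtype=np.uint8)
    for i, (sample_id, barcode, ev) in enumerate(rows):
        read = barcode + cfg.tr_tag + cfg.motif + _flank(genome, ev, len(cfg.motif), L)
        templates[i] = np.frombuffer(read[: cfg.read_length].encode(), dtype=np.uint8)

    row_of_read = np.repeat(np.arange(len(rows)), counts)
    n = len(row_of_read)

    truth = pd.DataFrame(
        {
            "read_id": [f"r{i:08d}" for i in range(n)],
            "sample_id": [rows[r][0] for r in row_of_read],
            "chrom": [rows[r][2].chrom for r in row_of_read],
            "pos": [rows[r][2].pos for r in row_of_read],
            "strand": [rows[r][2].strand for r in row_of_read],
            "is_primary": [rows[r][2].is_primary for r in row_of_read],
        }
    )

    with open(fastq_path, "w") as fh:
        for lo in range(0, n, chunk_size):
            hi = min(lo + chunk_size, n)
            block = templates[row_of_read[lo:hi]].copy()
            _apply_errors(block, cfg.error_rate, rng)
            out = []
            rid = truth["read_id"].values
            for j in range(hi - lo):
                out.append(
                    f"@{rid[lo + j]}\n{block[j].tobytes().decode()}\n+\n{qual}\n"
                )
            fh.write("".join(out))

    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    if manifest_path is not None:
        manifest.to_csv(manifest_path, sep="\t", index=False)
    return truth
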