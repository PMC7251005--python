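"""Screen statistics on insertion-call tables.

Implements the read-weighted summaries used to characterise a gene-trap
screen: strand proportions, feature-enrichment scores, per-clone window
clonality, gene assignment with insertion orientation, and trapped-gene
recovery across replicate libraries.

The feature enrichment score for a feature class c is

    score(c) = (reads in c / total reads) / (length of c / genome size)

so 1 means reads land in c exactly in proportion to the sequence it
covers, values above 1 mean enrichment. A trapped gene is a gene hit by
at least one sense-orientation insertion (cassette strand equal to gene
strand); only sense insertions disrupt the gene through the splice
acceptor, so recovery across libraries is counted on sense hits by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import GeneModel

__all__ = [
    "FeatureIndex",
    "FeatureEnrichment",
    "WindowClonality",
    "strand_proportion",
    "feature_enrichment",
    "enrichment_frame",
    "window_clonality",
    "window_clonality_table",
    "assign_genes",
    "trap_gene_table",
    "overlap_genes",
]

DEFAULT_CLASSES = ("exon", "intron", "intergenic", "transcription_unit")


class FeatureIndex:
    """Interval lookup over a non-overlapping gene annotation.

    Genes never overlap (generator guarantee), so membership reduces to
    a binary search against sorted span and exon boundaries per
    chromosome.
    """

    def __init__(self, genes: Sequence[GeneModel], chrom_lengths: dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self._spans: dict[str, tuple[np.ndarray, np.ndarray, list[str], list[str]]] = {}
        self._exons: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.chrom_lengths:
            g = sorted((x for x in genes if x.chrom == chrom), key=lambda x: x.start)
            for a, b in zip(g, g[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping genes {a.gene_id}/{b.gene_id}")
            self._spans[chrom] = (
                np.array([x.start for x in g], dtype=np.int64),
                np.array([x.end for x in g], dtype=np.int64),
                [x.gene_id for x in g],
                [x.strand for x in g],
            )
            ex = sorted((s, e) for x in g for s, e in x.exons)
            self._exons[chrom] = (
                np.array([s for s, _ in ex], dtype=np.int64),
                np.array([e for _, e in ex], dtype=np.int64),
            )

    # -- lengths ----------------------------------------------------------
    def class_lengths(self) -> dict[str, int]:
        """Exact lengths; exon + intron + intergenic partition the genome."""
        genome = sum(self.chrom_lengths.values())
        exon = int(sum((e - s).sum() for s, e in self._exons.values()))
        tu = int(sum((e - s).sum() for s, e, _, _ in self._spans.values()))
        lengths = {
            "exon": exon,
            "intron": tu - exon,
            "intergenic": genome - tu,
            "transcription_unit": tu,
        }
        assert lengths["exon"] + lengths["intron"] + lengths["intergenic"] == genome
        return lengths

    # -- membership -------------------------------------------------------
    def _member(self, table, chrom: str, pos: np.ndarray) -> np.ndarray:
        starts, ends = table[chrom][0], table[chrom][1]
        if len(starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        j = np.searchsorted(starts, pos, side="right") - 1
        return (j >= 0) & (pos < ends[np.clip(j, 0, None)])

    def in_exon(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return self._member(self._exons, chrom, pos)

    def in_tu(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return self._member(self._spans, chrom, pos)

    def gene_at(self, chrom: str, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(gene_id or None, gene strand or None) per position."""
        starts, ends, ids, strands = self._spans[chrom]
        gid = np.full(len(pos), None, dtype=object)
        gstrand = np.full(len(pos), None, dtype=object)
        if len(starts):
            j = np.searchsorted(starts, pos, side="right") - 1
            inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            for i in np.nonzero(inside)[0]:
                gid[i] = ids[j[i]]
                gstrand[i] = strands[j[i]]
        return gid, gstrand


@dataclass(frozen=True)
class FeatureEnrichment:
    feature_class: str
    reads_in_feature: int
    total_reads: int
    feature_length: int
    genome_size: int
    score: float


@dataclass(frozen=True)
class WindowClonality:
    clone_id: str
    window_size: int
    windows: pd.DataFrame  # chrom, window_index, read_count, proportion
    top: pd.DataFrame  # top-k rows padded with zero-proportion entries


def strand_proportion(calls: pd.DataFrame) -> tuple[float, float]:
    """Read-weighted (forward, reverse) fractions; they sum to 1."""
    if calls is None or len(calls) == 0:
        raise ValueError("no reads: cannot compute strand proportions")
    w = calls["read_count"] if "read_count" in calls else pd.Series(1, index=calls.index)
    fwd = float(w[calls["strand"] == "+"].sum())
    rev = float(w[calls["strand"] == "-"].sum())
    total = fwd + rev
    if total == 0:
        raise ValueError("no reads: cannot compute strand proportions")
    return fwd / total, rev / total


def feature_enrichment(
    calls: pd.DataFrame,
    features: FeatureIndex,
    classes: Sequence[str] = DEFAULT_CLASSES,
    lengths: dict[str, int] | None = None,
) -> list[FeatureEnrichment]:
    """Per-class enrichment scores of junction positions.

    A read counts toward a class when its junction coordinate falls in
    any interval of the class; counts are read-weighted. ``lengths``
    overrides the annotation-derived class lengths (e.g. to score
    against target-motif content instead of raw bp); the genome size is
    the total assembled length of the reference.
    """
    if len(calls) == 0:
        raise ValueError("no reads: cannot compute enrichment")
    class_lengths = dict(features.class_lengths())
    genome_size = sum(features.chrom_lengths.values())
    if lengths:
        class_lengths.update(lengths)
        if "__genome__" in lengths:
            genome_size = lengths["__genome__"]
    w = (calls["read_count"] if "read_count" in calls
         else pd.Series(1, index=calls.index))
    total = int(w.sum())
    counts = {c: 0 for c in classes}
    for chrom, sub in calls.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        sw = w.loc[sub.index].to_numpy()
        in_ex = features.in_exon(chrom, pos)
        in_tu = features.in_tu(chrom, pos)
        per_class = {
            "exon": in_ex,
            "intron": in_tu & ~in_ex,
            "intergenic": ~in_tu,
            "transcription_unit": in_tu,
            "whole_genome": np.ones(len(pos), dtype=bool),
        }
        for c in classes:
            if c not in per_class:
                raise KeyError(f"unknown feature class {c!r}")
            counts[c] += int(sw[per_class[c]].sum())
    class_lengths.setdefault("whole_genome", genome_size)
    out = []
    for c in classes:
        length = class_lengths[c]
        if length <= 0:
            raise ValueError(f"feature class {c!r} has zero length")
        score = (counts[c] / total) / (length / genome_size)
        out.append(FeatureEnrichment(c, counts[c], total, length, genome_size, score))
    return out


def enrichment_frame(scores: Sequence[FeatureEnrichment]) -> pd.DataFrame:
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(s) for s in scores])


def window_clonality(
    clone_calls: pd.DataFrame,
    clone_id: str,
    window_size: int = 100_000,
    k: int = 5,
) -> WindowClonality:
    """Read proportions of fixed genomic tiles for one clone.

    Tiles are [i*w, (i+1)*w) anchored at position 0 of each chromosome.
    The top-k list is sorted by read count descending, ties broken by
    (chrom, window_index), and padded with zero-proportion rows so it
    always has k entries.
    """
    if len(clone_calls) == 0 or clone_calls["read_count"].sum() == 0:
        raise ValueError(f"clone {clone_id!r} has zero reads")
    df = clone_calls.copy()
    df["window_index"] = df["pos"] // window_size
    win = (
        df.groupby(["chrom", "window_index"])["read_count"].sum().reset_index()
    )
    total = win["read_count"].sum()
    win["proportion"] = win["read_count"] / total
    win = win.sort_values(
        ["read_count", "chrom", "window_index"],
        ascending=[False, True, True], kind="mergesort",
    ).reset_index(drop=True)
    top = win.head(k).copy()
    while len(top) < k:
        top.loc[len(top)] = {"chrom": ".", "window_index": -1,
                             "read_count": 0, "proportion": 0.0}
    top.insert(0, "rank", range(1, k + 1))
    return WindowClonality(clone_id, window_size, win, top)


def window_clonality_table(
    calls: pd.DataFrame, window_size: int = 100_000, k: int = 5
) -> pd.DataFrame:
    """Tidy top-k window table across every clone in a call table."""
    frames = []
    for clone, sub in calls.groupby("sample_id"):
        wc = window_clonality(sub, clone, window_size, k)
        t = wc.top.copy()
        t.insert(0, "clone_id", clone)
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["clone_id", "rank", "chrom", "window_index",
                     "read_count", "proportion"])
    return pd.concat(frames, ignore_index=True)


def assign_genes(calls: pd.DataFrame, features: FeatureIndex) -> pd.DataFrame:
    """Decorate calls with gene_id and sense/antisense orientation.

    A call is assigned to the gene whose span contains its junction
    coordinate; orientation is 'sense' when the cassette strand equals
    the gene strand. Intergenic calls get gene_id None and no
    orientation.
    """
    out = calls.copy()
    gene_col = np.full(len(out), None, dtype=object)
    orient_col = np.full(len(out), None, dtype=object)
    for chrom, sub in out.groupby("chrom"):
        idx = sub.index.to_numpy()
        gid, gstrand = features.gene_at(chrom, sub["pos"].to_numpy())
        strands = sub["strand"].to_numpy()
        for i, (g, gs) in enumerate(zip(gid, gstrand)):
            if g is not None:
                gene_col[idx[i]] = g
                orient_col[idx[i]] = "sense" if strands[i] == gs else "antisense"
    out["gene_id"] = gene_col
    out["orientation"] = orient_col
    return out


def trap_gene_table(
    decorated_calls: pd.DataFrame,
    library_of: dict[str, str] | None = None,
    recovery_mode: str = "sense",
) -> pd.DataFrame:
    """Per-gene trapping summary across libraries.

    ``library_of`` maps sample_id to library id (identity when omitted,
    i.e. each sample is its own library). ``recovery_frequency`` counts
    libraries with at least one *sense* insertion in the gene
    (recovery_mode='sense'), or any insertion ('any'); 'both' reports
    both columns with the sense-based count as ``recovery_frequency``.
    """
    if recovery_mode not in ("sense", "any", "both"):
        raise ValueError("recovery_mode must be sense, any or both")
    df = decorated_calls[decorated_calls["gene_id"].notna()].copy()
    if library_of is not None:
        df["library"] = df["sample_id"].map(library_of)
    else:
        df["library"] = df["sample_id"]
    rows = []
    for gene, sub in df.groupby("gene_id"):
        total = int(sub["read_count"].sum())
        sense = int(sub.loc[sub["orientation"] == "sense", "read_count"].sum())
        libs_any = sorted(set(sub["library"]))
        libs_sense = sorted(set(sub.loc[sub["orientation"] == "sense", "library"]))
        rows.append(
            {
                "gene_id": gene,
                "total_reads": total,
                "sense_reads": sense,
                "sense_rate": sense / total,
                "n_insertion_sites": len(sub[["chrom", "pos", "strand"]].drop_duplicates()),
                "libraries_sense": ",".join(libs_sense),
                "libraries_any": ",".join(libs_any),
                "recovery_frequency_sense": len(libs_sense),
                "recovery_frequency_any": len(libs_any),
            }
        )
    out = pd.DataFrame(rows, columns=[
        "gene_id", "total_reads", "sense_reads", "sense_rate",
        "n_insertion_sites", "libraries_sense", "libraries_any",
        "recovery_frequency_sense", "recovery_frequency_any"])
    mode = "any" if recovery_mode == "any" else "sense"
    out["recovery_frequency"] = out[f"recovery_frequency_{mode}"]
    if recovery_mode != "both":
        out = out.drop(columns=["recovery_frequency_" + ("any" if mode == "sense" else "sense")])
    return out.sort_values("gene_id").reset_index(drop=True)


def overlap_genes(table: pd.DataFrame, n_libraries: int) -> list[str]:
    """Genes recovered in every one of ``n_libraries`` libraries."""
    if len(table) == 0:
        return []
    return sorted(table.loc[table["recovery_frequency"] >= n_libraries, "gene_id"])
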