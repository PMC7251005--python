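"""File I/O: annotation (GFF3/BED12), FASTQ streaming, atomic writes.

Internal coordinates are 0-based half-open throughout; GFF3 is converted
to 1-based inclusive on write and back on read, BED12 is native.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

from .simulate import GeneModel, SyntheticGenome

__all__ = [
    "write_gff3",
    "read_gff3",
    "write_bed12",
    "read_bed12",
    "iter_fastq",
    "atomic_write_text",
    "write_dataframe",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so partial outputs never appear."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_dataframe(df: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def write_gff3(
    genes: Sequence[GeneModel], genome: SyntheticGenome, path: str | Path
) -> None:
    lines = ["##gff-version 3"]
    for name, seq in genome.chromosomes:
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for g in genes:
        lines.append(
            "\t".join(
                [g.chrom, "trapscreen", "gene", str(g.start + 1), str(g.end),
                 ".", g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [g.chrom, "trapscreen", "exon", str(s + 1), str(e),
                     ".", g.strand, ".",
                     f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"]
                )
            )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/exon features back into GeneModel records."""
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                spans[a["ID"]] = (chrom, strand, int(start) - 1, int(end))
            elif ftype == "exon":
                exons.setdefault(a["Parent"], []).append((int(start) - 1, int(end)))
    genes = []
    for gid, (chrom, strand, s, e) in spans.items():
        ex = tuple(sorted(exons.get(gid, [(s, e)])))
        genes.append(GeneModel(gid, chrom, strand, s, e, ex))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - g.start) for s, _ in g.exons)
        lines.append(
            "\t".join(
                [g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                 str(g.start), str(g.end), "0", str(len(g.exons)), sizes, starts]
            )
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[:6]
            start, end = int(start), int(end)
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + sz) for o, sz in zip(offs, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: .gff/.gff3 or .bed."""
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return read_gff3(path)
    if p.endswith(".bed"):
        return read_bed12(path)
    raise ValueError(f"unrecognised annotation format: {path}")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file, gzipped or plain."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq
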