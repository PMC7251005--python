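"""Collapse quality-filtered aligned flanks into insertion-site calls.

Junctions are exact keys — the TTAA tetramer anchors the coordinate in
sequence, so no positional clustering window is applied. Read counts are
amplification-weighted abundances (no duplicate collapsing; the assay
has no UMIs), matching the read-proportion statistics downstream.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

__all__ = ["call_insertions", "per_clone_site_table", "calls_to_bed6"]

_CALL_COLS = ["chrom", "pos", "strand", "sample_id", "read_count",
              "fraction_of_sample_reads"]


def _to_frame(alignments) -> pd.DataFrame:
    if isinstance(alignments, pd.DataFrame):
        return alignments
    rows = [(a.chrom, a.pos, a.strand, a.sample_id) for a in alignments]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample_id"])


def call_insertions(alignments, min_reads: int = 1) -> pd.DataFrame:
    """Group filtered alignments by (chrom, pos, strand, sample).

    Calls with fewer than ``min_reads`` supporting reads are dropped;
    per-sample read fractions are computed over the retained calls so
    they sum to 1 per sample. Output is sorted by (chrom, pos, strand,
    sample), making the call table independent of input order.
    """
    df = _to_frame(alignments)
    if df.empty:
        return pd.DataFrame(columns=_CALL_COLS)
    calls = (
        df.groupby(["chrom", "pos", "strand", "sample_id"], sort=False)
        .size()
        .rename("read_count")
        .reset_index()
    )
    calls = calls[calls["read_count"] >= min_reads]
    totals = calls.groupby("sample_id")["read_count"].transform("sum")
    calls["fraction_of_sample_reads"] = calls["read_count"] / totals
    calls = calls.sort_values(["chrom", "pos", "strand", "sample_id"],
                              kind="mergesort").reset_index(drop=True)
    return calls[_CALL_COLS]


def per_clone_site_table(calls: pd.DataFrame,
                         clone_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """One row per clone: site count and the majority-read candidate.

    ``primary_candidate`` is the site with the most reads; ``majority``
    says whether it holds more than half the clone's reads, and ``tie``
    whether another site matches its read count (a tie is flagged, never
    silently resolved — the reported candidate is then the positionally
    first of the tied sites). Clones listed in ``clone_ids`` but absent
    from the calls get a row with n_sites 0.
    """
    rows = []
    for clone, sub in calls.groupby("sample_id"):
        sub = sub.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        total = int(sub["read_count"].sum())
        top_n = int(sub["read_count"].max())
        top = sub[sub["read_count"] == top_n].iloc[0]
        rows.append(
            {
                "clone_id": clone,
                "n_sites": len(sub),
                "total_reads": total,
                "primary_chrom": top["chrom"],
                "primary_pos": int(top["pos"]),
                "primary_strand": top["strand"],
                "primary_reads": top_n,
                "primary_fraction": top_n / total,
                "majority": top_n * 2 > total,
                "tie": int((sub["read_count"] == top_n).sum()) > 1,
            }
        )
    seen = {r["clone_id"] for r in rows}
    for clone in clone_ids or ():
        if clone not in seen:
            rows.append(
                {
                    "clone_id": clone, "n_sites": 0, "total_reads": 0,
                    "primary_chrom": None, "primary_pos": -1,
                    "primary_strand": None, "primary_reads": 0,
                    "primary_fraction": 0.0, "majority": False, "tie": False,
                }
            )
    return pd.DataFrame(rows).sort_values("clone_id").reset_index(drop=True)


def calls_to_bed6(calls: pd.DataFrame, motif_len: int = 4) -> str:
    """Render calls as BED6 text (name = sample, score = read count)."""
    lines = [
        "\t".join([r.chrom, str(r.pos), str(r.pos + motif_len), r.sample_id,
                   str(r.read_count), r.strand])
        for r in calls.itertuples(index=False)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
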