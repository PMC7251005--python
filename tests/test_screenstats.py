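"""Screen statistics: strand proportions, enrichment, clonality, trapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trapscreen.screenstats import (
    FeatureIndex,
    assign_genes,
    feature_enrichment,
    overlap_genes,
    strand_proportion,
    trap_gene_table,
    window_clonality,
    window_clonality_table,
)


def _calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample_id",
                                       "read_count"])


# ---------------------------------------------------------------------------
# strand proportion


def test_strand_proportion_arithmetic():
    calls = _calls([("chr1", 10, "+", "s", 3), ("chr1", 50, "-", "s", 1)])
    assert strand_proportion(calls) == (0.75, 0.25)
    only_fwd = _calls([("chr1", 10, "+", "s", 4)])
    assert strand_proportion(only_fwd) == (1.0, 0.0)


def test_strand_proportion_rejects_empty():
    with pytest.raises(ValueError, match="no reads"):
        strand_proportion(_calls([]))


def test_strand_proportion_converges_as_root_n():
    """Unbiased coin-flip strands give |p - 1/2| within 4 binomial SE at
    two sample sizes (the bound shrinks ~1/sqrt(n))."""
    rng = np.random.default_rng(51)
    for n in (1_000, 16_000):
        strands = rng.choice(["+", "-"], size=n)
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(n), "strand": strands,
             "sample_id": "s", "read_count": 1}
        )
        fwd, rev = strand_proportion(calls)
        assert abs(fwd - 0.5) <= 4 * (0.25 / n) ** 0.5
        assert fwd + rev == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# feature enrichment


def test_whole_genome_class_scores_exactly_one(features):
    calls = _calls([("chr1", 500, "+", "s", 7), ("chr2", 900, "-", "s", 3)])
    (fe,) = feature_enrichment(calls, features, classes=("whole_genome",))
    assert fe.score == 1.0


def test_enrichment_matches_hand_computation(features, genome):
    lengths = features.class_lengths()
    # one read in an exon of gene 1, three intergenic reads far from genes
    exonic = features._exons["chr1"][0][0]
    calls = _calls([("chr1", int(exonic), "+", "s", 1),
                    ("chr1", 5, "+", "s", 3)])
    scores = {
        fe.feature_class: fe
        for fe in feature_enrichment(calls, features)
    }
    g = genome.genome_size
    assert scores["exon"].score == pytest.approx(
        (1 / 4) / (lengths["exon"] / g))
    assert scores["intergenic"].score == pytest.approx(
        (3 / 4) / (lengths["intergenic"] / g))
    assert scores["intron"].reads_in_feature == 0


def test_enrichment_partition_consistency(features, genome, library):
    """Weighted mean of scores over a genome partition is exactly 1."""
    rows = [
        (e.chrom, e.pos, e.strand, c.clone_id, 5)
        for c in library for e in c.events
    ]
    scores = feature_enrichment(_calls(rows), features,
                                classes=("exon", "intron", "intergenic"))
    g = genome.genome_size
    total = sum(fe.score * fe.feature_length / g for fe in scores)
    assert total == pytest.approx(1.0, abs=1e-12)
    assert sum(fe.reads_in_feature for fe in scores) == scores[0].total_reads


@settings(max_examples=20, deadline=None, derandomize=True)
@given(counts=st.lists(st.integers(0, 50), min_size=4, max_size=4))
def test_enrichment_partition_property(features, genome, counts):
    if sum(counts) == 0:
        counts[0] = 1
    # place counts[i] reads in exon / intron / intergenic / exon-of-chr2
    fi = features
    pos_exon1 = int(fi._exons["chr1"][0][0])
    intron1 = None
    starts, ends = fi._exons["chr1"]
    spans = fi._spans["chr1"]
    intron1 = int(ends[0])  # just after first exon: inside gene, not exon
    assert fi.in_tu("chr1", np.array([intron1]))[0]
    rows = [("chr1", pos_exon1, "+", "s", counts[0]),
            ("chr1", intron1, "+", "s", counts[1]),
            ("chr1", 2, "+", "s", counts[2]),
            ("chr2", int(fi._exons["chr2"][0][0]), "+", "s", counts[3])]
    rows = [r for r in rows if r[4] > 0]
    scores = feature_enrichment(_calls(rows), fi,
                                classes=("exon", "intron", "intergenic"))
    g = genome.genome_size
    assert sum(fe.score * fe.feature_length / g for fe in scores) == pytest.approx(1.0)


def test_enrichment_error_cases(features):
    with pytest.raises(ValueError):
        feature_enrichment(_calls([]), features)
    calls = _calls([("chr1", 5, "+", "s", 1)])
    with pytest.raises(ValueError, match="zero length"):
        feature_enrichment(calls, features, classes=("exon",),
                           lengths={"exon": 0})


# ---------------------------------------------------------------------------
# window clonality


def test_single_insertion_clone_top1_is_one():
    calls = _calls([("chr1", 42_000, "+", "c1", 17)])
    wc = window_clonality(calls, "c1", window_size=100_000, k=5)
    props = wc.top["proportion"].tolist()
    assert props == [1.0, 0.0, 0.0, 0.0, 0.0]


def test_configured_skew_appears_in_top_windows():
    calls = _calls([("chr1", 10_000, "+", "c1", 90),
                    ("chr2", 250_000, "-", "c1", 10)])
    wc = window_clonality(calls, "c1", window_size=100_000, k=5)
    assert wc.top["proportion"].tolist()[:2] == [0.9, 0.1]
    assert abs(wc.windows["proportion"].sum() - 1.0) < 1e-9


def test_window_boundary_is_half_open():
    w = 100_000
    calls = _calls([("chr1", w - 1, "+", "c", 1), ("chr1", w, "+", "c", 1)])
    wc = window_clonality(calls, "c", window_size=w, k=2)
    assert sorted(wc.windows["window_index"]) == [0, 1]


def test_window_ties_broken_by_position():
    calls = _calls([("chr2", 5, "+", "c", 3), ("chr1", 250_000, "+", "c", 3)])
    wc = window_clonality(calls, "c", window_size=100_000, k=2)
    assert wc.top.iloc[0]["chrom"] == "chr1" and wc.top.iloc[0]["window_index"] == 2


def test_zero_read_clone_rejected():
    with pytest.raises(ValueError, match="zero reads"):
        window_clonality(_calls([]), "c")


def test_clonality_table_covers_all_clones(library):
    rows = [
        (e.chrom, e.pos, e.strand, c.clone_id, 7)
        for c in library for e in c.events
    ]
    t = window_clonality_table(_calls(rows), k=5)
    assert set(t["clone_id"]) == {c.clone_id for c in library}
    for _, sub in t.groupby("clone_id"):
        assert len(sub) == 5
        assert sub["proportion"].is_monotonic_decreasing


# ---------------------------------------------------------------------------
# gene assignment and trapping


def test_orientation_definitions(features, annotation):
    plus_gene = next(g for g in annotation if g.strand == "+")
    minus_gene = next(g for g in annotation if g.strand == "-")
    calls = _calls([
        (plus_gene.chrom, plus_gene.start + 10, "+", "s", 1),
        (plus_gene.chrom, plus_gene.start + 10, "-", "s", 1),
        (minus_gene.chrom, minus_gene.start + 10, "+", "s", 1),
    ])
    out = assign_genes(calls, features)
    assert out.iloc[0]["orientation"] == "sense"
    assert out.iloc[1]["orientation"] == "antisense"
    assert out.iloc[2]["orientation"] == "antisense"
    assert out.iloc[0]["gene_id"] == plus_gene.gene_id


def test_assignment_matches_intervaltree_oracle(features, genome, annotation):
    intervaltree = pytest.importorskip("intervaltree")
    trees = {}
    for g in annotation:
        trees.setdefault(g.chrom, intervaltree.IntervalTree()).addi(
            g.start, g.end, g.gene_id)
    rng = np.random.default_rng(61)
    rows = []
    for name, seq in genome.chromosomes:
        for p in rng.integers(0, len(seq), size=400):
            rows.append((name, int(p), "+", "s", 1))
    out = assign_genes(_calls(rows), features)
    for r in out.itertuples(index=False):
        hits = trees.get(r.chrom, intervaltree.IntervalTree())[r.pos]
        expected = next(iter(hits)).data if hits else None
        assert r.gene_id == expected


def test_sense_rate_arithmetic(features, annotation):
    g = next(g for g in annotation if g.strand == "+")
    calls = _calls([(g.chrom, g.start + 5, "+", "lib1", 8),
                    (g.chrom, g.start + 25, "-", "lib1", 2)])
    table = trap_gene_table(assign_genes(calls, features))
    row = table.set_index("gene_id").loc[g.gene_id]
    assert row["sense_rate"] == pytest.approx(0.8)
    assert row["total_reads"] == 10 and row["sense_reads"] == 8
    assert row["n_insertion_sites"] == 2


def test_overlap_requires_sense_in_every_library(features, annotation):
    g1 = next(g for g in annotation if g.strand == "+")
    g2 = next(g for g in annotation if g.strand == "-" and g.chrom != g1.chrom)
    rows = []
    for lib in ("lib1", "lib2", "lib3"):
        rows.append((g1.chrom, g1.start + 5, "+", lib, 4))  # sense everywhere
    rows.append((g2.chrom, g2.start + 5, "-", "lib1", 4))  # sense in one lib
    rows.append((g2.chrom, g2.start + 5, "+", "lib2", 4))  # antisense
    table = trap_gene_table(assign_genes(_calls(rows), features))
    assert overlap_genes(table, 3) == [g1.gene_id]
    row2 = table.set_index("gene_id").loc[g2.gene_id]
    assert row2["recovery_frequency"] == 1


def test_recovery_mode_both_reports_both_counts(features, annotation):
    g = next(g for g in annotation if g.strand == "-")
    rows = [(g.chrom, g.start + 5, "+", "lib1", 1),  # antisense
            (g.chrom, g.start + 5, "-", "lib2", 1)]  # sense
    table = trap_gene_table(assign_genes(_calls(rows), features),
                            recovery_mode="both")
    row = table.set_index("gene_id").loc[g.gene_id]
    assert row["recovery_frequency_any"] == 2
    assert row["recovery_frequency_sense"] == 1


def test_sense_rate_stable_under_subsampling(features, annotation):
    """Binomial thinning of read counts leaves the sense rate unchanged
    in expectation (checked at large n)."""
    g = next(g for g in annotation if g.strand == "+")
    n_sense, n_anti = 80_000, 20_000
    calls = _calls([(g.chrom, g.start + 5, "+", "lib1", n_sense),
                    (g.chrom, g.start + 25, "-", "lib1", n_anti)])
    full = trap_gene_table(assign_genes(calls, features))
    rng = np.random.default_rng(62)
    thinned = calls.copy()
    thinned["read_count"] = rng.binomial(thinned["read_count"], 0.5)
    sub = trap_gene_table(assign_genes(thinned, features))
    r_full = full.iloc[0]["sense_rate"]
    r_sub = sub.iloc[0]["sense_rate"]
    se = (r_full * (1 - r_full) / (0.5 * (n_sense + n_anti))) ** 0.5
    assert abs(r_sub - r_full) < 5 * se
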