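"""End-to-end orchestration: simulate -> process -> map -> call -> stats.

Every stage writes its outputs atomically under the configured output
directory, and a run manifest records the config hash, package version,
and per-stage read-conservation counts (input reads = assigned + each
discard category; assigned = mapped + unmapped; mapped = kept + dropped
by the MAPQ filter).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, simulate
from .calling import call_insertions, calls_to_bed6, per_clone_site_table
from .mapping import build_index, filter_mapq, map_flanks
from .readproc import ProcessingParams, process_reads
from .screenstats import (
    FeatureIndex,
    assign_genes,
    enrichment_frame,
    feature_enrichment,
    overlap_genes,
    strand_proportion,
    trap_gene_table,
    window_clonality_table,
)

log = logging.getLogger("trapscreen")

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline", "make_report"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SimulateBlock:
    n_chrom: int = 2
    chrom_length: int = 100_000
    gc: float = 0.42
    n_genes: int = 40
    exons_per_gene: int = 3
    n_clones: int = 15
    secondary_rate: float = 0.1
    tu_bias: float = 5.0
    n_reads: int = 50_000
    read_length: int = 64
    error_rate: float = 0.005
    tr_tag: str = "CGTCAGTCGAGC"
    target_motif: str = "TTAA"
    barcode_length: int = 8
    end_margin: int = 100


@dataclass
class Thresholds:
    mapq_min: int = 30  # strict: keep mapq > mapq_min
    min_reads: int = 1
    barcode_mismatch: int = 1
    tag_mismatch: int = 2
    motif_mismatch: int = 1
    min_flank: int = 20
    max_mismatch: int = 2
    k: int = 13


@dataclass
class StatsBlock:
    window_size: int = 100_000
    top_k: int = 5
    recovery_mode: str = "sense"


@dataclass
class PipelineConfig:
    outdir: str = "trapscreen_out"
    seed: int = 1
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    thresholds: Thresholds = field(default_factory=Thresholds)
    stats: StatsBlock = field(default_factory=StatsBlock)
    # pre-existing inputs; when unset the simulate stage provides them
    genome: str | None = None
    annotation: str | None = None
    fastq: str | None = None
    barcode_manifest: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        except yaml.YAMLError as e:
            raise ConfigError(f"bad YAML in {path}: {e}")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, d):
            known = {f.name for f in dataclasses.fields(klass)}
            bad = set(d) - known
            if bad:
                raise ConfigError(f"unknown {klass.__name__} keys: {sorted(bad)}")
            return klass(**d)

        cfg = cls(
            outdir=raw.get("outdir", "trapscreen_out"),
            seed=int(raw.get("seed", 1)),
            simulate=build(SimulateBlock, raw.get("simulate", {}) or {}),
            thresholds=build(Thresholds, raw.get("thresholds", {}) or {}),
            stats=build(StatsBlock, raw.get("stats", {}) or {}),
            genome=raw.get("genome"),
            annotation=raw.get("annotation"),
            fastq=raw.get("fastq"),
            barcode_manifest=raw.get("barcode_manifest"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("genome", "annotation", "fastq", "barcode_manifest"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if self.stats.recovery_mode not in ("sense", "any", "both"):
            raise ConfigError("stats.recovery_mode must be sense, any or both")
        if not 0 <= self.simulate.error_rate < 0.5:
            raise ConfigError("simulate.error_rate must be in [0, 0.5)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as e:  # noqa: BLE001 - re-tag with stage name
                raise StageError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(cfg: PipelineConfig, outdir: Path):
    s = cfg.simulate
    genome = simulate.generate_genome(
        s.n_chrom, s.chrom_length, s.gc, seed=cfg.seed, motif=s.target_motif
    )
    annotation = simulate.generate_annotation(
        genome, s.n_genes, s.exons_per_gene, seed=cfg.seed + 1
    )
    library = simulate.simulate_library(
        genome, annotation, s.n_clones, s.secondary_rate, s.tu_bias,
        seed=cfg.seed + 2, barcode_length=s.barcode_length,
        motif=s.target_motif, end_margin=s.end_margin,
    )
    rcfg = simulate.ReadSimConfig(
        n_reads=s.n_reads, read_length=s.read_length, error_rate=s.error_rate,
        tr_tag=s.tr_tag, motif=s.target_motif, seed=cfg.seed + 3,
    )
    genome.write_fasta(outdir / "genome.fa")
    io.write_gff3(annotation, genome, outdir / "annotation.gff3")
    io.write_bed12(annotation, outdir / "annotation.bed")
    simulate.simulate_splinkerette_reads(
        library, genome, rcfg,
        fastq_path=outdir / "reads.fastq",
        truth_path=outdir / "truth.tsv",
        manifest_path=outdir / "barcodes.tsv",
    )
    return genome, annotation, library


@_stage("process")
def _run_process(cfg: PipelineConfig, outdir: Path, fastq, manifest_path):
    manifest_df = pd.read_csv(manifest_path, sep="\t")
    manifest = dict(zip(manifest_df["sample_id"], manifest_df["barcode"]))
    t = cfg.thresholds
    params = ProcessingParams(
        barcode_mismatch=t.barcode_mismatch, tag_mismatch=t.tag_mismatch,
        motif_mismatch=t.motif_mismatch, min_flank=t.min_flank,
        tr_tag=cfg.simulate.tr_tag, motif=cfg.simulate.target_motif,
    )
    passed, counts, per_sample = process_reads(
        io.iter_fastq(fastq), manifest, params, max_mismatch=t.barcode_mismatch
    )
    io.write_dataframe(
        pd.DataFrame(sorted(counts.items()), columns=["reason", "reads"]),
        outdir / "discard_report.tsv",
    )
    io.write_dataframe(
        pd.DataFrame(sorted(per_sample.items()), columns=["sample_id", "reads"]),
        outdir / "reads_per_sample.tsv",
    )
    return passed, counts


@_stage("map")
def _run_map(cfg: PipelineConfig, outdir: Path, genome, passed):
    t = cfg.thresholds
    index = build_index(genome, k=t.k)
    aln, unmapped = map_flanks(
        ((r.read_id, r.sample_id, r.flank) for r in passed), index, t.max_mismatch
    )
    kept = filter_mapq(aln, t.mapq_min)
    io.write_dataframe(kept, outdir / "alignments.tsv")
    return aln, kept, unmapped


@_stage("call")
def _run_call(cfg: PipelineConfig, outdir: Path, kept):
    calls = call_insertions(kept, min_reads=cfg.thresholds.min_reads)
    io.write_dataframe(calls, outdir / "calls.tsv")
    io.atomic_write_text(outdir / "calls.bed", calls_to_bed6(calls))
    return calls


@_stage("stats")
def _run_stats(cfg: PipelineConfig, outdir: Path, genome, annotation, calls, library):
    st = cfg.stats
    features = FeatureIndex(annotation, {n: len(s) for n, s in genome.chromosomes})
    fwd, rev = strand_proportion(calls)
    enrich = enrichment_frame(feature_enrichment(calls, features))
    clon = window_clonality_table(calls, st.window_size, st.top_k)
    decorated = assign_genes(calls, features)
    genes = trap_gene_table(decorated, recovery_mode=st.recovery_mode)
    n_libraries = calls["sample_id"].nunique()
    overlap = overlap_genes(genes, n_libraries)
    clones = per_clone_site_table(
        calls, [c.clone_id for c in library] if library else None
    )

    io.write_dataframe(enrich, outdir / "enrichment.tsv")
    io.write_dataframe(clon, outdir / "clonality.tsv")
    io.write_dataframe(genes, outdir / "trap_genes.tsv")
    io.write_dataframe(clones, outdir / "clone_sites.tsv")
    summary = {
        "genome_size": genome.genome_size,
        "strand_proportion": {"forward": fwd, "reverse": rev},
        "enrichment": enrich.to_dict(orient="records"),
        "clonality_top_windows": clon.to_dict(orient="records"),
        "overlap_genes": overlap,
        "n_libraries": int(n_libraries),
    }
    io.atomic_write_text(outdir / "summary.json", json.dumps(summary, indent=2))
    return summary


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the JSON summary as a dict.

    When ``cfg.genome``/``cfg.fastq``/... are unset the simulate stage
    generates them; otherwise the provided files are used and the
    simulate stage is skipped.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    simulating = cfg.fastq is None
    if simulating:
        genome, annotation, library = _run_simulate(cfg, outdir)
        fastq, manifest_path = outdir / "reads.fastq", outdir / "barcodes.tsv"
    else:
        if cfg.genome is None or cfg.barcode_manifest is None:
            raise ConfigError("fastq given but genome/barcode_manifest missing")
        genome = simulate.SyntheticGenome.from_fasta(cfg.genome)
        annotation = io.read_annotation(cfg.annotation) if cfg.annotation else []
        library = None
        fastq, manifest_path = cfg.fastq, cfg.barcode_manifest

    passed, counts = _run_process(cfg, outdir, fastq, manifest_path)
    aln, kept, unmapped = _run_map(cfg, outdir, genome, passed)
    calls = _run_call(cfg, outdir, kept)
    if len(calls) == 0:
        raise StageError("stage 'call' failed: no insertion calls survive filtering")
    summary = _run_stats(cfg, outdir, genome, annotation, calls, library)

    n_input = sum(counts.values())
    conservation = {
        "input_reads": n_input,
        "assigned_reads": counts["none"],
        "discards": {k: v for k, v in counts.items() if k != "none"},
        "mapped_reads": int(len(aln)),
        "unmapped_reads": int(unmapped),
        "mapq_filtered_reads": int(len(kept)),
        "called_reads": int(calls["read_count"].sum()),
    }
    assert conservation["assigned_reads"] + sum(
        conservation["discards"].values()
    ) == n_input
    assert conservation["mapped_reads"] + conservation["unmapped_reads"] == (
        conservation["assigned_reads"]
    )
    manifest = {
        "trapscreen_version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": cfg.sha256(),
        "read_conservation": conservation,
    }
    io.atomic_write_text(outdir / "run_manifest.json", json.dumps(manifest, indent=2))
    return summary


def run_bulk_strand_assay(
    n_reads: int,
    seed: int,
    workdir: str | Path,
    n_chrom: int = 2,
    chrom_length: int = 100_000,
    gc: float = 0.42,
    error_rate: float = 0.005,
    read_length: int = 64,
    mapq_min: int = 30,
    genome_seed: int | None = None,
) -> dict:
    """Strand-balance benchmark: a bulk coverage assay with fair-coin strands.

    Emulates sequencing a transposed cell population in bulk: ``n_reads``
    independent insertions are drawn uniformly over the genome's TTAA
    sites with an unbiased cassette strand, synthesised as splinkerette
    reads, and pushed through the full pipeline (demultiplex, trim, map,
    strict MAPQ filter, call). Returns the read-weighted forward-strand
    fraction of the surviving reads together with the counts needed for
    a binomial error bound.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    genome = simulate.generate_genome(
        n_chrom, chrom_length, gc,
        seed=seed if genome_seed is None else genome_seed,
    )
    events = simulate.simulate_bulk_events(genome, None, n_reads, seed=seed + 1)
    rcfg = simulate.ReadSimConfig(
        n_reads=n_reads, read_length=read_length, error_rate=error_rate,
        seed=seed + 2,
    )
    fastq = workdir / "bulk_reads.fastq"
    manifest_path = workdir / "bulk_barcodes.tsv"
    simulate.simulate_splinkerette_reads(
        events, genome, rcfg, fastq_path=fastq, manifest_path=manifest_path
    )
    mdf = pd.read_csv(manifest_path, sep="\t")
    manifest = dict(zip(mdf["sample_id"], mdf["barcode"]))
    params = ProcessingParams(tr_tag=rcfg.tr_tag, motif=rcfg.motif)
    passed, counts, _ = process_reads(io.iter_fastq(fastq), manifest, params)
    index = build_index(genome)
    aln, unmapped = map_flanks(
        ((r.read_id, r.sample_id, r.flank) for r in passed), index
    )
    kept = filter_mapq(aln, mapq_min)
    calls = call_insertions(kept)
    fwd, rev = strand_proportion(calls)
    n = int(calls["read_count"].sum())
    return {
        "forward_fraction": fwd,
        "reverse_fraction": rev,
        "n_reads_simulated": n_reads,
        "n_reads_retained": n,
        "n_unmapped": int(unmapped),
        "three_se": 3.0 * (0.25 / n) ** 0.5,
    }


def make_report(outdir: str | Path) -> str:
    """Human-readable summary assembled from the pipeline's output files."""
    outdir = Path(outdir)
    spath = outdir / "summary.json"
    if not spath.exists():
        raise StageError(f"missing stage output: {spath}")
    summary = json.loads(spath.read_text())
    lines = ["# trapscreen report", ""]
    sp = summary["strand_proportion"]
    lines += [
        f"Genome size: {summary['genome_size']} bp",
        "",
        "## Strand proportion (read-weighted)",
        f"forward: {sp['forward']:.4%}   reverse: {sp['reverse']:.4%}",
        "",
        "## Feature enrichment scores",
    ]
    for r in summary["enrichment"]:
        lines.append(
            f"{r['feature_class']:>20}: score {r['score']:.3f} "
            f"({r['reads_in_feature']}/{r['total_reads']} reads, "
            f"{r['feature_length']}/{r['genome_size']} bp)"
        )
    lines += ["", "## Per-clone top windows (read proportion)"]
    by_clone: dict[str, list] = {}
    for r in summary["clonality_top_windows"]:
        by_clone.setdefault(r["clone_id"], []).append(r)
    for clone, rows in sorted(by_clone.items()):
        tops = " ".join(f"{r['proportion']:.3f}" for r in rows)
        lines.append(f"{clone}: {tops}")
    lines += ["", f"## Genes trapped in all {summary['n_libraries']} libraries"]
    if summary["overlap_genes"]:
        lines += [", ".join(summary["overlap_genes"])]
    else:
        lines += ["no genes recovered in all libraries"]
    text = "\n".join(lines) + "\n"
    io.atomic_write_text(outdir / "report.txt", text)
    return text
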