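"""Shared fixtures: a small genome, annotation, clonal library and reads.

Everything is generated programmatically with fixed seeds so the suite
needs no data files; session scope keeps the heavier simulations to one
run each.
"""

import pandas as pd
import pytest

from trapscreen import io as tio
from trapscreen.mapping import build_index
from trapscreen.readproc import ProcessingParams, process_reads
from trapscreen.screenstats import FeatureIndex
from trapscreen.simulate import (
    ReadSimConfig,
    generate_annotation,
    generate_genome,
    simulate_library,
    simulate_splinkerette_reads,
)


@pytest.fixture(scope="session")
def genome():
    return generate_genome(2, 30_000, gc=0.42, seed=7)


@pytest.fixture(scope="session")
def annotation(genome):
    return generate_annotation(genome, 12, exons_per_gene=3, seed=8)


@pytest.fixture(scope="session")
def features(genome, annotation):
    return FeatureIndex(annotation, {n: len(s) for n, s in genome.chromosomes})


@pytest.fixture(scope="session")
def library(genome, annotation):
    return simulate_library(
        genome, annotation, n_clones=20, secondary_rate=0.1, tu_bias=1.0, seed=9
    )


@pytest.fixture(scope="session")
def clean_reads(genome, library, tmp_path_factory):
    """Error-free reads for the library, plus the ground-truth table."""
    d = tmp_path_factory.mktemp("clean_reads")
    cfg = ReadSimConfig(n_reads=10_000, error_rate=0.0, seed=10)
    truth = simulate_splinkerette_reads(
        library, genome, cfg,
        fastq_path=d / "reads.fastq",
        truth_path=d / "truth.tsv",
        manifest_path=d / "barcodes.tsv",
    )
    return {"dir": d, "cfg": cfg, "truth": truth,
            "fastq": d / "reads.fastq", "manifest": d / "barcodes.tsv"}


@pytest.fixture(scope="session")
def manifest(clean_reads):
    mdf = pd.read_csv(clean_reads["manifest"], sep="\t")
    return dict(zip(mdf["sample_id"], mdf["barcode"]))


@pytest.fixture(scope="session")
def clean_processed(clean_reads, manifest):
    passed, counts, per_sample = process_reads(
        tio.iter_fastq(clean_reads["fastq"]), manifest, ProcessingParams()
    )
    return passed, counts, per_sample


@pytest.fixture(scope="session")
def index(genome):
    return build_index(genome, k=13)
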