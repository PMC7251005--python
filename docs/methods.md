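# Methods

## Generative model of the synthetic screen

The simulator emulates a one-insertion-per-cell gene-trap screen in
haploid cells, at three levels.

**Genome and annotation.** Chromosome sequences are i.i.d. bases at a
configurable GC fraction (default 0.42, mouse-like); every chromosome is
guaranteed at least one TTAA. Genes are placed without overlap by a
stars-and-bars draw of inter-gene gaps (placement is exact, not
rejection-sampled, whenever the total gene length fits), with exon
boundaries drawn as distinct interior cut points so that the first exon
starts at the gene start and the last ends at the gene end. As a result
exon + intron + intergenic lengths partition the genome exactly — the
property the feature-enrichment score's consistency check relies on.
Overlapping or nested gene models are deliberately out of scope; with
them the partition would need an ownership rule the enrichment formula
does not define.

**Clonal structure.** Each clone carries exactly one *primary* insertion
at a TTAA site, drawn with weight `tu_bias` (default 5) inside
transcription units and 1 outside — the transposon's known integration
preference — with a fair-coin cassette strand. Incomplete transposase
self-inactivation is modelled as `k` secondary insertions per clone with
`P(k) = (1 − s)·s^k` (default `s = 0.1`, so ~90% of clones are
single-insertion). Clone abundances are a flat Dirichlet draw by default
(uneven clone expansion); `abundance="uniform"` gives equal fractions
for determinism-sensitive experiments. Sites within `end_margin`
(default 100 bp) of a chromosome end are excluded from the candidate
pool up front, so a read flank can never run off the sequence whichever
strand the cassette takes; this keeps the ground truth fixed rather than
resampling positions at read-synthesis time.

**Reads.** Every read is `barcode | TR tag | TTAA | genomic flank`,
truncated to `read_length` (default 64 bp: 8 + 12 + 4 + 40), with i.i.d.
substitution errors (default 0.005; an error never reproduces the
original base). The flank is the genomic sequence downstream of the
junction on the cassette strand, reverse-complemented for '−'
insertions — TTAA is its own reverse complement, so the junction motif
reads identically from both sides. Reads are allocated to (clone, event)
pairs by a single multinomial draw with probability ∝ clone abundance ×
event weight, where the primary event has relative weight 1 and each
secondary 0.1; with `k` secondaries the primary therefore holds
`1/(1 + 0.1k)` of the clone's reads (≥ 90% for k ≤ 1), reproducing the
observed dominance of the first insertion. `primary_fraction` overrides
this with a fixed primary share. Barcodes are greedy random codes with
pairwise Hamming distance ≥ 3 (default length 8), which is what makes
one-mismatch demultiplexing unambiguous; for hundreds of clones the
greedy search needs length 10.

A separate *bulk* mode models the population-scale coverage assay
(~10⁷ cells transposed and sequenced under a single library barcode):
each of `n` independent events gets one read. Bulk libraries are where
strand balance is a meaningful diagnostic; small clone panels are
dominated by a few abundances and legitimately sit far from 50%.

What the simulator does **not** model: PCR duplicates and chimeras,
quality-score-dependent error profiles, indels, paired-end structure,
repeat-rich reference sequence. Tests passing on this generator
therefore certify the pipeline's logic (demultiplexing, junction
anchoring, MAPQ filtering, the statistics), not its robustness to
repetitive genomes or amplification artefacts.

## Read processing

The read layout is deterministic, so processing is fixed-offset Hamming
comparison, not alignment: barcode within 1 mismatch (manifest barcodes
must be pairwise > 2 mismatches apart, which makes the assignment unique
or empty), TR tag within 2, junction motif within 1, then the flank must
be ≥ 20 bp (`min_flank`; shorter flanks cannot map uniquely on realistic
genomes). Failures are per-read discard reasons, never exceptions, and
the category counts conserve the input read count exactly. Reads failing
junction validation are dropped rather than rescued because the motif is
the positional anchor of the eventual call.

## Mapping and the MAPQ filter

The internal mapper is seed-and-verify over an exact k-mer index of the
forward reference strand (default `k = 13`), querying the flank and its
reverse complement and verifying candidates by early-exit Hamming
comparison. Because `k ≤ len(flank)/(max_mismatch+1)` gives the flank
`max_mismatch + 1` disjoint seeds, any placement within the budget
(default 2) leaves at least one seed exact, so the mapper is *provably
identical* to a brute-force scan of every placement — the equivalence is
asserted exhaustively in the tests against an independent
sliding-window implementation. Ties are never broken arbitrarily:
`n_hits` is reported and mapping quality is binary, 60 for a unique best
placement and 0 otherwise. Alignments from an external aligner can be
adapted from SAM/BAM instead, keeping the aligner's own MAPQ.

The junction coordinate is always the 0-based start of the TTAA tetramer
on the forward strand: placement start − 4 for '+' cassettes, placement
end for '−'. One canonical key makes reads from both orientations of the
same event collapse to the same site. The screen's quality filter keeps
alignments with MAPQ **strictly** greater than 30 (the inequality is
taken literally); on the internal mapper this is exactly the unique-hit
condition.

## Calling and statistics

Calls are exact groupings of (chrom, junction, strand, sample) — the
sequence-anchored junction makes a ±1 clustering window unnecessary —
with an optional `min_reads` depth filter (default 1: read counts are
amplification-weighted abundances; no duplicate collapsing is attempted
because the assay as modelled has no UMIs). Calling is order-independent
and read-conserving by construction.

Statistics are read-weighted throughout. Feature classes default to
exon / intron / intergenic / transcription-unit; class lengths come from
the annotation partition but can be overridden (the calibration test
scores uniform-over-TTAA insertions against classes measured in TTAA
sites, where every score's expectation is exactly 1). Genome size is the
total assembled FASTA length, with no gap correction. Clonality windows
are fixed 100-kb tiles anchored at position 0 of each chromosome
(windows are half-open, so a junction at a tile boundary belongs to the
right-hand tile); top-5 lists are padded with zero-proportion rows and
ties ranked by genomic position. A gene counts as trapped only by
sense-orientation insertions; `recovery_mode` switches cross-library
recovery counting between sense-only (default, per the trapping
mechanism), any-orientation, or both reported side by side.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere internally; GFF3 is
  converted at the boundary.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline stages derive per-stage seeds as small fixed offsets
  from the config seed, and a fixed seed reproduces byte-identical
  FASTQ/TSV/JSON outputs.
* Degenerate inputs fail loudly: empty read sets, zero-length feature
  classes, zero-read clones and manifests violating the distance
  precondition all raise before any statistic is produced.
* Problem sizes in the test and acceptance runs: bulk strand-balance at
  10⁶ reads on a 2 × 100 kb genome, recovery at 500 uniform-abundance
  clones (barcode length 10) and 10⁵ reads, enrichment calibration at
  10⁵ insertions, clonality at 15 clones × 3 × 10⁴ reads, mapper
  equivalence exhaustive over ~1,500 noisy flanks on a 60 kb genome.
  These sizes give the binomial error bounds quoted in each test while
  keeping a full run in the minutes range on one CPU.

## Known limitations

The internal mapper is ungapped; indel-containing flanks belong on the
external-aligner path. Genome repeats are handled honestly (ties →
MAPQ 0 → filtered) but the simulator rarely produces them, so repeat
behaviour is exercised only by constructed fixtures. Common-insertion-
site statistics across animals or tumours, GO enrichment and any
expression follow-up are out of scope.
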