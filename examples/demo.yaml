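# Demo pipeline configuration: simulate a small clonal gene-trap library
# and run every stage. Finishes in well under a minute on one CPU.
outdir: trapscreen_demo
seed: 1
simulate:
  n_chrom: 2
  chrom_length: 50000
  gc: 0.42
  n_genes: 20
  exons_per_gene: 3
  n_clones: 15
  secondary_rate: 0.1
  tu_bias: 5.0
  n_reads: 20000
  read_length: 64
  error_rate: 0.005
thresholds:
  mapq_min: 30        # keep alignments with MAPQ strictly above this
  min_reads: 1
stats:
  window_size: 100000
  top_k: 5
  recovery_mode: sense
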