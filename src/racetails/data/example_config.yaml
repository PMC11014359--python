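# Example run configuration.  All sequences here are SYNTHETIC examples;
# real analyses must supply the experiment's reference windows, adapter
# delimiter, and L1 subfamily diagnostic table.
references: synthetic_references.fasta
sample_sheet: example_samples.tsv
diagnostics: synthetic_diagnostics.tsv
reference_meta:
  L1rep: {primer_offset: 180}
  GAPDH: {primer_offset: 180}
  PABPC4: {primer_offset: 180}
  L1_consensus: {primer_offset: 180}
layout:
  umi_len: 15
  delimiter: CTGC   # placeholder; experiment-specific
  index_len: 6
  index_in_r2: false
tolerances:
  index: 1
  delimiter: 1
  anchor_mismatch_rate: 0.05
  tail: 0
  min_anchor: 12
  max_gap: 3
  min_mean_q: 20
window: 80
dedup_mode: exact
stratify: reference
seed: 0
simulate:
  class_probs: {A: 0.70, AU: 0.15, U: 0.02, NONE: 0.13}
  a_len_dist: {name: nbinom, mean: 45, dispersion: 5}
  u_len_dist: {name: geometric, mean: 2}
  copy_dist: {name: shifted_poisson, mean: 3}
  error_rate: 0.001
  read_len_r1: 150
  read_len_r2: 100
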