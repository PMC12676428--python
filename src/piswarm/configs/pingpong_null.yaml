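# Primary-only control matched to the pingpong fixture: identical
# cluster and sampling, no planted mate pairs.
name: pingpong_null
seed: 5
genome:
  gc_content: 0.42
  intergenic_gap: [300, 600]
clusters:
  - cluster_id: c1
    strand_mode: bidirectional
    padding: 200
    extra_length: 3000
pirna_sampling:
  total_reads: 20000
  length_range: [26, 32]
  u1_probability: 0.8
  background_fraction: 0.05
  pingpong_fraction: 0.0
  emission:
    "cluster:c1": 1.0
expression:
  n_non_targets: 0
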