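# Rank-abundance panel: 88 head genes under a Zipf law holding 70% of
# the targeting weight (rank 1 = 12%), plus 250 uniform tail genes,
# each gene with a perfect antisense copy in one shared cluster.
name: fig1a
seed: 11
genome:
  gc_content: 0.42
  length: 800000
  intergenic_gap: [40, 120]
target_panel:
  host_cluster: cpanel
  n_head: 88
  head_coverage: 0.70
  top1_fraction: 0.12
  n_tail: 250
  utr5_length: 60
  cds_length: 220
  utr3_length: 140
  tsd_length: 10
clusters:
  - cluster_id: cpanel
    strand_mode: plus
    padding: 150
    spacer: 30
pirna_sampling:
  total_reads: 120000
  length_range: [26, 32]
  u1_probability: 0.8
  background_fraction: 0.03
expression:
  effect_size_top: 1.0
  effect_size_lower: 0.1
  sd: 0.5
  n_non_targets: 400
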