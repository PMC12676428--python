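# Smoke-test fixture: one 3-exon gene, one decoy, one cluster carrying a
# single antisense pseudogene fragment.
name: minimal
seed: 7
genome:
  gc_content: 0.42
  intergenic_gap: [200, 500]
genes:
  - gene_id: GENEA
    n_exons: 3
    exon_length: [200, 300]
    intron_length: [150, 300]
    utr5_length: 80
    utr3_length: 200
    strand: "+"
  - gene_id: DECOY1
    n_exons: 1
    exon_length: [400, 500]
    utr5_length: 60
    utr3_length: 120
    strand: "-"
clusters:
  - cluster_id: c1
    strand_mode: plus
    padding: 150
    spacer: 80
pgfs:
  - pgf_id: geneA_c1
    source_gene: GENEA
    host_cluster: c1
    exon_range: [2, 3]
    five_prime_truncation: 40
    divergence: 0.05
    tsd_length: 14
    orientation: antisense
pirna_sampling:
  total_reads: 5000
  length_range: [26, 32]
  u1_probability: 0.8
  background_fraction: 0.1
  emission:
    "pgf:geneA_c1": 1.0
expression:
  effect_size_top: 1.0
  effect_size_lower: 0.1
  sd: 0.5
  n_non_targets: 50
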