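# Partly processed fragment: exons 2-6 with the intron between exons 5
# and 6 retained, mirroring a retrotransposition caught mid-splicing.
name: ago2like
seed: 42
genome:
  gc_content: 0.42
  intergenic_gap: [300, 700]
genes:
  - gene_id: AGO2L
    n_exons: 6
    exon_length: [200, 300]
    intron_length: [150, 350]
    utr5_length: 100
    utr3_length: 300
    strand: "+"
  - gene_id: DECOY1
    n_exons: 2
    exon_length: [250, 350]
    intron_length: [150, 300]
    utr5_length: 80
    utr3_length: 180
    strand: "-"
clusters:
  - cluster_id: piC_A
    strand_mode: minus
    padding: 200
    spacer: 100
pgfs:
  - pgf_id: ago2_picA
    source_gene: AGO2L
    host_cluster: piC_A
    exon_range: [2, 6]
    five_prime_truncation: 40
    divergence: 0.04
    tsd_length: 15
    orientation: antisense
    include_intron: true
    intron_after: 5
pirna_sampling:
  total_reads: 20000
  length_range: [26, 32]
  u1_probability: 0.8
  background_fraction: 0.05
  emission:
    "pgf:ago2_picA": 1.0
expression:
  effect_size_top: 1.2
  effect_size_lower: 0.1
  sd: 0.5
  n_non_targets: 100
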