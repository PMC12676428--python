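# One dominant cluster/target pair: two antisense pseudogene fragments of
# the same gene in two clusters at 81:19 emission, 5% divergence, 14-nt
# target-site duplications, fragment spanning exons 3-5 and 5'-truncated.
name: spin1like
seed: 42
genome:
  gc_content: 0.42
  length: 120000
  intergenic_gap: [300, 700]
genes:
  - gene_id: SPIN1L
    n_exons: 6
    exon_length: [200, 320]
    intron_length: [150, 400]
    utr5_length: 120
    utr3_length: 400
    strand: "+"
  - gene_id: DECOY1
    n_exons: 4
    exon_length: [180, 260]
    intron_length: [150, 300]
    utr5_length: 90
    utr3_length: 250
    strand: "-"
  - gene_id: DECOY2
    n_exons: 1
    exon_length: [500, 700]
    utr5_length: 80
    utr3_length: 200
    strand: "+"
clusters:
  - cluster_id: piC_A
    strand_mode: plus
    padding: 200
    spacer: 100
  - cluster_id: piC_B
    strand_mode: plus
    padding: 200
    spacer: 100
pgfs:
  - pgf_id: spin1_picA
    source_gene: SPIN1L
    host_cluster: piC_A
    exon_range: [3, 5]
    five_prime_truncation: 60
    divergence: 0.05
    tsd_length: 14
    orientation: antisense
  - pgf_id: spin1_picB
    source_gene: SPIN1L
    host_cluster: piC_B
    exon_range: [3, 5]
    five_prime_truncation: 60
    divergence: 0.05
    tsd_length: 14
    orientation: antisense
pirna_sampling:
  total_reads: 200000
  length_range: [26, 32]
  u1_probability: 0.8
  background_fraction: 0.05
  emission:
    "pgf:spin1_picA": 0.81
    "pgf:spin1_picB": 0.19
expression:
  effect_size_top: 1.0
  effect_size_lower: 0.1
  sd: 0.5
  n_non_targets: 200
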