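# Methods

## The targeting model

A piRNA is treated as a slicer guide: complementarity is evaluated over
a fixed guide window, by default nucleotides 2–21 counted 1-based from
the piRNA 5′ end, against the mRNA sense sequence. A target site is a
transcript position where the reverse complement of that 20-mer matches
with at most `max_mismatches` (default 1) Hamming mismatches. The
comparison is ungapped — a mismatch *count* over a fixed nt range only
makes sense for an ungapped duplex — and strict Watson–Crick: G:U
wobble counts as a mismatch because the rule specifies mismatches, not
pairing energies. Position 1 is exempt (it sits in the PIWI MID-domain
pocket, not paired with the target), as is any 3′ tail beyond the
window. piRNAs shorter than the window end cannot be evaluated and are
excluded with a tally. The predicted slice position is the transcript
base paired to guide nt 10, the 3′ side of the scissile phosphate.

Matching runs through a pigeonhole seed index: the window is split into
`max_mismatches + 1` contiguous seeds (equal sizes, remainder on the
last), so any admissible site leaves at least one seed exact; exact
k-mer lookup plus full-window verification therefore recovers the
brute-force site set exactly. Both the index and the brute-force
scanner ship, and the suite asserts set equality on randomized and
planted instances.

## Weights, ranking, groups

All downstream quantities weight piRNAs by read count (abundance); a
`unique` switch counts distinct sequences instead. The abundance
reading is what makes molecules-per-cell arithmetic meaningful
(fraction × ~10⁷ piRNA molecules per spermatocyte). A piRNA targeting
several genes splits its weight equally between them by default
(`split` policy), keeping per-gene fractions interpretable as
proportions of the targeting pool; the `full` policy credits each gene
fully and renormalizes. Ranking ties break lexicographically by gene id
so output is deterministic. The top-target set is the smallest rank
prefix whose cumulative fraction reaches the coverage threshold
(default 0.70), which is also how the expression groups (top / lower /
non-targets) are formed.

Metagene profiles place each site at the transcript base paired to the
piRNA 5′ end (site end − 1, the piRNA being antisense), scale each of
5′UTR/CDS/3UTR to 20 bins (`bin = floor(n_bins·offset/feature_len)`),
normalize each gene's 60-bin vector to sum 1, and average across genes.
Genes lacking any of the three features are excluded from profiles (but
retained everywhere else); genes without CDS annotation carry a
`CDS-absent` label throughout.

## Source attribution

Genomic mapping is exact and full-length on both strands — piRNAs are
parsed from single-stranded precursors, so every authentic read is a
genome substring, and allowing mismatches would only blur source
assignment. A piRNA with k occurrences contributes 1/k at each. A hit
belongs to the cluster containing its 5′-end coordinate (deterministic
for edge-straddling reads); everything else is `NON_PIC`. Targeting
piRNAs with no perfect hit (possible once sequencing errors are
simulated) are reported `UNMAPPED` and excluded from decomposition
fractions unless requested. The per-gene decomposition lists sources in
descending fraction and summarizes them as top/second/third, pooled
minor clusters (<5% each), and non-cluster weight. A (piRNA, gene) pair
is *cis* when some perfect hit of the piRNA overlaps the gene's
exon-union locus, else *trans*.

## Pseudogene fragments and TSDs

Fragments are found by optimal local alignment (biotite's
Smith–Waterman) of cluster sequence against each spliced transcript,
in both orientations. Scoring: match +2, mismatch −3; a gap of length L
costs 5 + 2(L−1) (the first gapped column opens the gap). Suboptimal
blocks are collected greedily — align, split the query at the
footprint, recurse — then collinear blocks are chained. A chain passing
`min_len` (100 nt) aligned columns and `min_identity` (80%) becomes a
fragment call. Neither threshold is a literature value; they are set so
that copies with ≤20% divergence are found while random hits are not,
and both are exposed on the CLI.

Anatomy calls: `five_prime_truncated` when the alignment starts more
than 50 nt (parameter) into the transcript — the signature of abortive
LINE-machinery reverse transcription. A cluster-side insertion (a long
query-only gap run inside a block, or the gap between chained blocks)
that aligns to annotated intron sequence at ≥80% identity marks the
copy `partly_processed` and names the retained intron; such recognized
intron columns are removed from the identity denominator, since they
align to intron rather than mRNA. Without intronic insertions the copy
is `processed`. Intron recognition is annotation-based, not ab initio.
One caveat: an optimal local alignment may overshoot the planted copy
by a few chance flanking matches, so exon lists can occasionally
include a neighbouring ordinal and identities sit marginally below
100% even for exact copies.

TSD detection searches for the longest exact direct repeat with one
copy ending within `boundary_slack` (5 nt) of the insertion 5′ boundary
and one beginning within slack of the 3′ boundary, copies ≤ 30 nt,
minimum 8 nt. Exact repeats only: the staggered-nick integration
mechanism copies the site verbatim, and exactness is what makes the
maximality property (no single-base extension possible) well defined.
Ties at the maximal length resolve to the copies closest to the
boundaries, then leftmost.

Pairwise locus identity pools matches over all chained blocks in the
better orientation; loci with no block above the score threshold are
reported not-comparable rather than 0%.

## Signatures

Position frequency matrices are read-count weighted with ragged
normalization: position p's denominator includes only records of length
≥ p, so mixed-length pools have well-defined logos. `u1_fraction` is
freq(U, 1) and `a10_fraction` freq(A, 10). The ping-pong profile
accumulates, for every opposite-strand pair of genomic hits on a
chromosome, the product of their weights at offset = 5′-end overlap
(1–20 nt); z10 compares offset 10 against the other 19 offsets
((w10 − mean)/sd). The z-score background choice is field-standard,
not derived from a formula in any source.

## KS comparisons

D is computed exactly by merging the two sorted samples and taking the
supremum of |ECDF₁ − ECDF₂| over all jump points (covering both
one-sided deviations, so ties are handled). The p-value is the
Kolmogorov distribution at effective size n₁n₂/(n₁+n₂)
(`scipy.stats.kstwo.sf(D, round(en))`), the same asymptotic form the
reference two-sample implementation uses — the suite asserts agreement
to 1e-9 — with a warning below 8 observations per sample. Differential
expression itself is consumed, never computed: any gene-level table of
log2 fold changes works.

## The synthetic-data generator

The generator emulates the data this pipeline is designed for, and its
defaults are the study conditions of the shipped fixtures:

* **Genome/annotation**: i.i.d. bases at configured GC (0.42), genes
  with drawn exon/intron lengths and UTR-defined CDS spans, clusters
  laid out without overlap; a configured genome length pads the
  chromosome with intergenic sequence. spin1like and fig1a use 120 kb
  and 800 kb so that genes and clusters are sparse features, as in a
  real genome — otherwise uniform background reads overlap annotation
  in antisense at unrealistic rates.
* **Insertions**: spliced exon ranges of a source transcript
  (optionally with one retained intron), 5′-truncated, point-diverged,
  written antisense to the host cluster's precursor strand, flanked by
  an exact TSD of the configured length. The single-base positions
  immediately outside the planted duplication are forced to differ from
  the corresponding insert ends, so the planted TSD length is maximal
  by construction.
* **Divergence** is placed quasi-regularly: `round(rate·L)` positions
  at even spacing with jitter, gaps capped at 24 nt. At the configured
  rates (≥ ~4%) every 26–32-nt read then contains a diverged position
  and maps uniquely to its source fragment. With i.i.d. mutations at
  5%, ~23% of reads would be identical to the parental mRNA over their
  whole length and multi-map to the gene locus and any sister fragment,
  which irrecoverably distorts cluster attribution at the planted-value
  level (expected top share ~0.73 for a planted 0.81). Aged, fixed
  pseudogenes in real clusters are similarly saturated with diagnostic
  differences. Below ~4% the spacing cap cannot be honoured and the
  uniqueness guarantee lapses.
* **Reads**: 5′ starts uniform within the emitting source and strand,
  lengths uniform on 26–32. `u1_probability` is the marginal
  probability that a read starts with U, implemented by choosing the
  start from U-start vs non-U-start candidate positions — never by
  editing bases, so every read remains an exact genome substring and
  perfect mapping stays lossless. Background reads come from random
  genomic positions; ping-pong mates sit on the opposite strand with an
  exact 10-nt 5′ overlap to a sampled primary read. An `error_rate`
  knob substitutes bases post hoc to exercise the UNMAPPED path
  (default off).
* **fig1a panel**: 88 head genes under a Zipf law whose exponent is
  solved (Brent) so the head holds exactly 70% of emission and rank 1
  holds 12%, plus 250 uniform tail genes; every gene gets a perfect
  antisense copy in one shared cluster.
* **Expression**: top targets (cumulative-coverage prefix of the
  planted weights) draw log2FC from N(effect_top, sd), lower targets
  from N(effect_lower, sd), non-targets from N(0, sd); padj is a
  BH-adjusted one-sample z against zero. This is a caricature of a
  DESeq2 output — mean shift only, no dispersion/significance
  structure.

What passing on these fixtures does **not** show: performance on real
annotation complexity (overlapping genes, many isoforms, repeats),
piRNA length distributions with real mode structure, sequencing error
and adapter artifacts, or genome-scale multi-mapping. The fixtures are
identifiability constructions: they make planted parameters exactly
recoverable so that pipeline defects are not absorbed into "biology".

## Fixture scales and determinism

spin1like runs at 200,000 reads (two fragments at 81:19 emission, 5%
divergence, 14-nt TSDs), fig1a at 120,000 reads over 338 genes;
recovered values at these depths sit within ±1 pp of the planted
fractions (dominant-cluster share runs ~0.5–1 pp below 0.81 because
background antisense reads and the two fragments' particular mutation
layouts both perturb the ratio). All randomness flows from one
`numpy.random.default_rng` seed; identical seeds reproduce outputs
byte-for-byte. The acceptance script derives a second stream for the
fig1a fixture as `(seed + 1000003) mod 2³¹`.

## Known limitations

* Ungapped matching only; bulged target sites are out of scope.
* Genomic mapping is exact-match only (by design, see above).
* The seed index is in-memory and per-transcriptome; it is built for
  desk-scale transcriptomes, not a full mammalian annotation.
* TSDs are exact repeats; degenerate duplications are not called.
* `partly_processed` requires intron annotation; unannotated introns
  are reported as plain insertions (identity penalty, no label).
* Everything is single-threaded.
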