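"""Local alignment vs an independent Gotoh DP, PGF anatomy and TSD calls."""

import numpy as np
import pytest

from piswarm import (
    ClusterAnnotation,
    GeneModel,
    Genome,
    Scoring,
    build_transcriptome,
    detect_tsd,
    local_align,
    pairwise_identity,
    revcomp,
    scan_pgf,
    simulate,
)
from piswarm.pgf import _align_once
from piswarm.simulate import mutate_spaced, random_dna

SCORING = Scoring()


def gotoh_local_score(a: str, b: str, sc: Scoring = SCORING) -> int:
    """Quadratic affine-gap Smith-Waterman reference.

    A gap of length L costs |gap_open| + (L-1)*|gap_extend|: the first
    gapped column opens the gap.
    """
    neg = -(10 ** 9)
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=int)
    E = np.full((n + 1, m + 1), neg, dtype=int)  # gap in a
    F = np.full((n + 1, m + 1), neg, dtype=int)  # gap in b
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + sc.gap_open, E[i][j - 1] + sc.gap_extend)
            F[i][j] = max(H[i - 1][j] + sc.gap_open, F[i - 1][j] + sc.gap_extend)
            sub = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlignment:
    def test_identical_sequences_align_full_length(self, rng):
        s = random_dna(rng, 100)
        (aln,) = local_align(s, s, min_score=40)[:1]
        assert aln.percent_identity == 100.0
        assert (aln.q_start, aln.q_end) == (0, 100)
        assert aln.score == 200

    def test_five_substitutions_give_95_percent(self, rng):
        a = random_dna(rng, 100)
        b = list(a)
        for i in (10, 30, 50, 70, 90):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        aln = local_align(a, "".join(b))[0]
        assert aln.n_columns == 100
        assert aln.percent_identity == pytest.approx(95.0)

    def test_scores_match_gotoh_dp_on_random_pairs(self, rng):
        """Production aligner equals an independent quadratic DP."""
        for _ in range(25):
            a = random_dna(rng, int(rng.integers(30, 70)))
            b = random_dna(rng, int(rng.integers(30, 70)))
            aln = _align_once(a, b, SCORING)
            got = 0 if aln is None else aln.score
            assert got == gotoh_local_score(a, b)

    def test_gapped_instances_match_gotoh(self, rng):
        for _ in range(10):
            core = random_dna(rng, 50)
            a = random_dna(rng, 10) + core + random_dna(rng, 10)
            cut = int(rng.integers(10, 40))
            gap = int(rng.integers(1, 8))
            b = core[:cut] + core[cut + gap:]
            aln = _align_once(a, b, SCORING)
            assert aln.score == gotoh_local_score(a, b)

    def test_symmetry_of_identity_and_score(self, rng):
        a = random_dna(rng, 120)
        b, _ = mutate_spaced(a, 0.08, rng)
        x = _align_once(a, b, SCORING)
        y = _align_once(b, a, SCORING)
        assert x.score == y.score
        assert x.percent_identity == pytest.approx(y.percent_identity)

    def test_antisense_orientation_reported(self, rng):
        a = random_dna(rng, 80)
        b = random_dna(rng, 30) + revcomp(a) + random_dna(rng, 30)
        best = local_align(a, b)[0]
        assert best.strand_relation == "antisense"
        assert (best.q_start, best.q_end) == (0, 80)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            _align_once("", "ACGT", SCORING)


def build_cluster_fixture(rng, divergence=0.0, exon_range=(3, 5), truncation=60):
    """A synthetic cluster holding an antisense copy of a gene's exons."""
    from conftest import make_random_gene

    genome0, gene = make_random_gene(rng, n_exons=6, exon_len=(150, 250),
                                     utr5=60, utr3=200)
    from piswarm import build_transcript

    tr = build_transcript(gene, genome0)
    mask = (tr.exon_index >= exon_range[0]) & (tr.exon_index <= exon_range[1])
    idx = np.flatnonzero(mask)
    segment = tr.sequence[idx[0] + truncation: idx[-1] + 1]
    insert = revcomp(segment if divergence == 0 else mutate_spaced(segment, divergence, rng)[0])
    pad = 200
    chrom = genome0["chr1"] + random_dna(rng, 300)
    cstart = len(chrom)
    cseq = random_dna(rng, pad) + insert + random_dna(rng, pad)
    chrom += cseq
    genome = Genome({"chr1": chrom})
    clustr = ClusterAnnotation("c1", "chr1", cstart, cstart + len(cseq), "plus")
    return genome, gene, clustr


class TestScanPGF:
    def test_exact_antisense_copy_recovered_with_anatomy(self, rng):
        genome, gene, cl = build_cluster_fixture(rng)
        trs = build_transcriptome([gene], genome)
        (hit,) = scan_pgf(cl, genome, trs, {"g1": gene})
        assert hit.target_gene_id == "g1"
        # a local alignment may overshoot the planted copy by a few
        # lucky flanking matches, so identity is near-perfect, not exact
        assert hit.percent_identity >= 98.5
        assert set(hit.exons_covered) >= {3, 4, 5}
        assert hit.five_prime_truncated
        assert hit.processed_state == "processed"
        assert hit.strand_relation == "antisense"

    def test_diverged_copy_keeps_planted_identity(self, rng):
        genome, gene, cl = build_cluster_fixture(rng, divergence=0.05)
        trs = build_transcriptome([gene], genome)
        (hit,) = scan_pgf(cl, genome, trs, {"g1": gene})
        assert hit.percent_identity >= 90.0
        assert hit.percent_identity == pytest.approx(95.0, abs=1.5)

    def test_unrelated_cluster_yields_no_hits(self, rng):
        from conftest import make_random_gene

        genome0, gene = make_random_gene(rng, n_exons=3)
        chrom = genome0["chr1"] + random_dna(rng, 2000)
        genome = Genome({"chr1": chrom})
        cl = ClusterAnnotation("c1", "chr1", len(genome0["chr1"]) + 100,
                               len(chrom) - 100, "plus")
        trs = build_transcriptome([gene], genome)
        assert scan_pgf(cl, genome, trs, {"g1": gene}) == []

    def test_retained_intron_marks_partly_processed(self):
        res = simulate("ago2like")
        trs = build_transcriptome(res.genes, res.genome)
        hits = scan_pgf(res.clusters[0], res.genome, trs, res.gene_models())
        hit = next(h for h in hits if h.target_gene_id == "AGO2L")
        assert hit.processed_state == "partly_processed"
        assert hit.retained_introns == [5]
        assert hit.strand_relation == "antisense"
        assert hit.exons_covered == [2, 3, 4, 5, 6]
        assert hit.percent_identity >= 90.0


class TestDetectTSD:
    def make_insertion(self, rng, tsd_len, insert_len=300):
        tsd = random_dna(rng, tsd_len)
        left = random_dna(rng, 100)
        insert = random_dna(rng, insert_len)
        right = random_dna(rng, 100)
        # guard the two single-base extension points
        if left[-1] == insert[-1]:
            left = left[:-1] + ("A" if insert[-1] != "A" else "C")
        if right[0] == insert[0]:
            right = ("A" if insert[0] != "A" else "C") + right[1:]
        chrom = left + tsd + insert + tsd + right
        start = len(left) + tsd_len
        return Genome({"chr1": chrom}), (start, start + insert_len)

    @pytest.mark.parametrize("tsd_len", [14, 20])
    def test_planted_duplication_length_recovered_exactly(self, rng, tsd_len):
        genome, interval = self.make_insertion(rng, tsd_len)
        res = detect_tsd(genome, "chr1", interval)
        assert res.repeat_length == tsd_len
        assert res.offset_slack_used == 0

    def test_maximality_of_returned_repeat(self, rng):
        genome, interval = self.make_insertion(rng, 14)
        res = detect_tsd(genome, "chr1", interval)
        seq = genome["chr1"]
        (ls, le), (rs, re) = res.left_copy, res.right_copy
        assert seq[ls:le] == seq[rs:re]
        assert seq[ls - 1] != seq[rs - 1]   # cannot extend left
        assert seq[le] != seq[re]           # cannot extend right

    def test_random_flanks_give_no_call(self, rng):
        # P(spurious >= 8-mer exact repeat in 30-nt windows) is negligible
        for _ in range(10):
            genome = Genome({"chr1": random_dna(rng, 600)})
            assert detect_tsd(genome, "chr1", (250, 350)) is None

    def test_insufficient_flank_is_an_error(self, rng):
        genome = Genome({"chr1": random_dna(rng, 100)})
        with pytest.raises(ValueError):
            detect_tsd(genome, "chr1", (10, 90))

    def test_simulator_anatomy_detected_end_to_end(self):
        res = simulate("minimal")
        chrom, s, e = res.pgf_interval("geneA_c1")
        tsd = detect_tsd(res.genome, chrom, (s, e))
        assert tsd.repeat_length == 14


class TestPairwiseIdentity:
    def test_identical_loci(self, rng):
        a = random_dna(rng, 1500)
        ident, segs = pairwise_identity(a, a)
        assert ident == 100.0
        assert len(segs) >= 1

    def test_ten_percent_divergence(self, rng):
        a = random_dna(rng, 2000)
        b, _ = mutate_spaced(a, 0.10, rng)
        ident, _ = pairwise_identity(a, b)
        assert ident == pytest.approx(90.0, abs=1.5)

    def test_unrelated_loci_not_comparable(self, rng):
        ident, segs = pairwise_identity(random_dna(rng, 800), random_dna(rng, 900))
        assert ident is None and segs.empty
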