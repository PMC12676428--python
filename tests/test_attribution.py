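"""Perfect genomic mapping, cluster attribution and cis/trans labels."""

import numpy as np
import pandas as pd
import pytest

from piswarm import (
    ClusterAnnotation,
    GeneModel,
    Genome,
    GenomicHit,
    attribute_sources,
    classify_cis_trans,
    collapse_reads,
    decompose_gene,
    map_perfect,
    revcomp,
)
from piswarm.attribution import NON_PIC, map_perfect_naive, pic_fraction
from piswarm.matching import SITE_COLUMNS, SiteTable
from piswarm.simulate import random_dna

from test_convergence import site_rows


class TestMapPerfect:
    def test_planted_plus_strand_hit(self, rng):
        g = random_dna(rng, 500)
        read = g[100:130]
        (hit,) = map_perfect(collapse_reads([read]), Genome({"chr1": g}))
        assert (hit.chrom, hit.start, hit.strand, hit.weight_share) == ("chr1", 100, "+", 1.0)

    def test_revcomp_occurrence_is_minus_strand(self, rng):
        g = random_dna(rng, 500)
        read = revcomp(g[200:228])
        (hit,) = map_perfect(collapse_reads([read]), Genome({"chr1": g}))
        assert (hit.start, hit.strand) == (200, "-")
        assert hit.five_prime_pos == 227  # 5' end of a minus read is its right edge

    def test_multimapper_shares_sum_to_one(self, rng):
        seg = random_dna(rng, 30)
        g = random_dna(rng, 200) + seg + random_dna(rng, 200) + seg + random_dna(rng, 50)
        hits = map_perfect(collapse_reads([seg]), Genome({"chr1": g}))
        assert len(hits) == 2
        assert sum(h.weight_share for h in hits) == pytest.approx(1.0)

    def test_equivalent_to_naive_scan(self, rng):
        g = random_dna(rng, 20000)
        reads = [random_dna(rng, int(rng.integers(26, 33))) for _ in range(30)]
        reads += [g[i: i + 28] for i in range(500, 5000, 450)]
        reads += [revcomp(g[i: i + 30]) for i in range(700, 4000, 700)]
        pool = collapse_reads(reads)
        genome = Genome({"chr1": g})
        fast = {(h.pirna, h.chrom, h.start, h.strand, round(h.weight_share, 9))
                for h in map_perfect(pool, genome)}
        slow = {(h.pirna, h.chrom, h.start, h.strand, round(h.weight_share, 9))
                for h in map_perfect_naive(pool, genome)}
        assert fast == slow


def cluster(cid, start, end, chrom="chr1"):
    return ClusterAnnotation(cid, chrom, start, end, "plus")


class TestAttributeSources:
    def test_hit_inside_cluster(self):
        hits = [GenomicHit("A" * 26, "chr1", 150, "+", 1.0)]
        w = attribute_sources(hits, [cluster("c1", 100, 300)])
        assert w == {"A" * 26: {"c1": 1.0}}

    def test_split_between_cluster_and_non_pic(self):
        hits = [
            GenomicHit("A" * 26, "chr1", 150, "+", 0.5),
            GenomicHit("A" * 26, "chr1", 900, "+", 0.5),
        ]
        w = attribute_sources(hits, [cluster("c1", 100, 300)])
        assert w["A" * 26] == {"c1": 0.5, NON_PIC: 0.5}

    def test_five_prime_rule_for_edge_straddling_minus_hit(self):
        # minus-strand read starting left of the cluster but whose 5' end
        # (right edge) lies inside it belongs to the cluster
        hits = [GenomicHit("A" * 26, "chr1", 90, "-", 1.0)]
        w = attribute_sources(hits, [cluster("c1", 100, 300)])
        assert w["A" * 26] == {"c1": 1.0}

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            attribute_sources([], [cluster("c1", 0, 200), cluster("c2", 150, 400)])

    def test_per_pirna_weights_sum_to_one(self, rng):
        hits = []
        for i in range(20):
            seq = random_dna(rng, 28)
            k = int(rng.integers(1, 4))
            for _ in range(k):
                hits.append(GenomicHit(seq, "chr1", int(rng.integers(0, 5000)), "+", 1 / k))
        w = attribute_sources(hits, [cluster("c1", 0, 1000), cluster("c2", 2000, 3000)])
        for seq, d in w.items():
            assert sum(d.values()) == pytest.approx(1.0)


class TestDecomposeGene:
    def test_single_source_is_top_one(self):
        sites = site_rows([("A" * 26, "g1", 0, 10)])
        w = {"A" * 26: {"c1": 1.0}}
        dec = decompose_gene("g1", sites, w)
        assert dec.summary["top"] == 1.0
        assert dec.top_cluster() == "c1"

    def test_minor_rule_pools_small_clusters(self):
        rows, weights = [], {}
        for seq, (label, frac) in zip(
            ["A" * 26, "C" * 26, "G" * 26],
            [("c1", 0.81), ("c2", 0.15), ("c3", 0.04)],
        ):
            rows.append((seq, "g1", 0, int(frac * 100)))
            weights[seq] = {label: 1.0}
        dec = decompose_gene("g1", site_rows(rows), weights)
        assert dec.summary["top"] == pytest.approx(0.81)
        assert dec.summary["second"] == pytest.approx(0.15)
        assert dec.summary["third"] == 0.0
        assert dec.summary["minor_lt5"] == pytest.approx(0.04)

    def test_weight_conservation(self, rng):
        rows, weights = [], {}
        for i in range(30):
            seq = random_dna(rng, 27)
            rows.append((seq, "g1", int(rng.integers(0, 100)), int(rng.integers(1, 20))))
            shares = rng.dirichlet(np.ones(3))
            weights[seq] = {"c1": shares[0], "c2": shares[1], NON_PIC: shares[2]}
        dec = decompose_gene("g1", site_rows(rows), weights)
        assert sum(f for _, f in dec.entries) == pytest.approx(1.0)

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError):
            decompose_gene("nope", site_rows([("A" * 26, "g1", 0, 1)]), {})

    def test_unmapped_excluded_by_default(self):
        sites = site_rows([("A" * 26, "g1", 0, 10), ("C" * 26, "g1", 5, 10)])
        w = {"A" * 26: {"c1": 1.0}}  # C... has no genomic hit
        dec = decompose_gene("g1", sites, w)
        assert dec.summary["top"] == 1.0
        assert dec.unmapped_weight == 10
        inc = decompose_gene("g1", sites, w, include_unmapped=True)
        assert inc.summary["unmapped"] == pytest.approx(0.5)

    def test_multimapping_neutrality(self, rng):
        """Duplicating a cluster's sequence halves each hit's share but
        leaves the per-piRNA total and the decomposition unchanged."""
        seg = random_dna(rng, 400)
        g1 = random_dna(rng, 100) + seg + random_dna(rng, 600)
        g2 = g1 + seg + random_dna(rng, 100)
        read = seg[50:78]
        pool = collapse_reads([read])
        c = [cluster("c1", 100, 500)]
        w1 = attribute_sources(map_perfect(pool, Genome({"chr1": g1})), c)
        w2 = attribute_sources(map_perfect(pool, Genome({"chr1": g2})), c)
        assert w1[read] == {"c1": 1.0}
        assert w2[read] == {"c1": 0.5, NON_PIC: 0.5}
        assert sum(w2[read].values()) == pytest.approx(1.0)


class TestCisTrans:
    def test_labels_follow_genomic_overlap(self, rng):
        gene = GeneModel("g1", "chr1", "+", [(100, 400)], cds_span=(150, 350))
        sites = site_rows([("A" * 26, "g1", 0, 5), ("C" * 26, "g1", 10, 5)])
        hits = [
            GenomicHit("A" * 26, "chr1", 200, "-", 1.0),   # inside the locus
            GenomicHit("C" * 26, "chr1", 5000, "+", 1.0),  # distant cluster
        ]
        df = classify_cis_trans(sites, hits, {"g1": gene})
        labels = dict(zip(df["pirna"], df["label"]))
        assert labels["A" * 26] == "cis"
        assert labels["C" * 26] == "trans"
        assert df.attrs["trans_fraction"] == pytest.approx(0.5)


class TestPicFraction:
    def test_weighted_cluster_share(self):
        sites = site_rows([("A" * 26, "g1", 0, 30), ("C" * 26, "g1", 5, 10)])
        w = {"A" * 26: {"c1": 1.0}, "C" * 26: {NON_PIC: 1.0}}
        assert pic_fraction(sites, w) == pytest.approx(0.75)
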