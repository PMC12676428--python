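"""Ranking, top-target sets, metagene binning and abundance arithmetic."""

import numpy as np
import pandas as pd
import pytest

from piswarm import (
    Genome,
    GeneModel,
    aggregate_by_gene,
    build_transcript,
    collapse_reads,
    metagene_profile,
    molecules_per_cell,
    targeting_fraction,
    top_target_set,
)
from piswarm.matching import SITE_COLUMNS, SiteTable
from piswarm.simulate import random_dna


def site_rows(rows):
    """rows: (pirna, gene, start, count) -> SiteTable (window length 20)."""
    records = [
        {
            "pirna": p,
            "gene_id": g,
            "start": s,
            "end": s + 20,
            "mismatch_count": 0,
            "mismatch_positions": "",
            "slice_pos": s + 11,
            "count": c,
        }
        for p, g, s, c in rows
    ]
    return SiteTable(pd.DataFrame(records, columns=SITE_COLUMNS))


class TestTargetingFraction:
    def test_bounds(self):
        seqs = ["A" * 26, "C" * 26, "G" * 26]
        pool = collapse_reads(seqs)
        none = SiteTable(pd.DataFrame(columns=SITE_COLUMNS))
        assert targeting_fraction(pool, none) == 0.0
        all_sites = site_rows([(s, "g", 0, 1) for s in seqs])
        assert targeting_fraction(pool, all_sites) == 1.0

    def test_read_weighting_vs_unique(self):
        pool = collapse_reads(["A" * 26] * 9 + ["C" * 26])
        sites = site_rows([("A" * 26, "g", 0, 9)])
        assert targeting_fraction(pool, sites) == 0.9
        assert targeting_fraction(pool, sites, unique=True) == 0.5

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            targeting_fraction(collapse_reads([]), site_rows([]))


class TestAggregateByGene:
    def test_single_pirna_single_gene(self):
        table = aggregate_by_gene(site_rows([("p" * 26, "g1", 5, 10)]))
        row = table.iloc[0]
        assert row["targeting_weight"] == 10
        assert row["fraction_of_targeting"] == 1.0
        assert row["span_nt"] == 20  # single site spans the window

    def test_split_policy_halves_shared_pirna(self):
        t = site_rows([("p" * 26, "g1", 0, 8), ("p" * 26, "g2", 3, 8)])
        table = aggregate_by_gene(t, policy="split").set_index("gene_id")
        assert table.loc["g1", "fraction_of_targeting"] == 0.5
        assert table.loc["g2", "targeting_weight"] == 4.0

    def test_full_policy_renormalises(self):
        t = site_rows(
            [("p" * 26, "g1", 0, 6), ("p" * 26, "g2", 3, 6), ("q" * 26, "g1", 9, 6)]
        )
        table = aggregate_by_gene(t, policy="full").set_index("gene_id")
        # g1 credited 12, g2 credited 6 -> fractions 2/3 and 1/3
        assert table.loc["g1", "fraction_of_targeting"] == pytest.approx(2 / 3)
        assert np.isclose(table["fraction_of_targeting"].sum(), 1.0)

    @pytest.mark.parametrize("policy", ["split", "full"])
    def test_fractions_sum_to_one(self, rng, policy):
        rows = []
        for i in range(40):
            p = random_dna(rng, 26)
            for g in rng.choice(10, size=int(rng.integers(1, 4)), replace=False):
                rows.append((p, f"g{g}", int(rng.integers(0, 400)), int(rng.integers(1, 50))))
        table = aggregate_by_gene(site_rows(rows), policy=policy)
        assert np.isclose(table["fraction_of_targeting"].sum(), 1.0, atol=1e-9)
        assert table["rank"].tolist() == list(range(1, len(table) + 1))

    def test_span_is_union_not_sum(self):
        t = site_rows([("p" * 26, "g1", 0, 1), ("q" * 26, "g1", 10, 1)])
        assert aggregate_by_gene(t).iloc[0]["span_nt"] == 30  # [0,30) union

    def test_tie_break_is_lexicographic(self):
        t = site_rows([("p" * 26, "gb", 0, 5), ("q" * 26, "ga", 0, 5)])
        assert aggregate_by_gene(t)["gene_id"].tolist() == ["ga", "gb"]

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            aggregate_by_gene(site_rows([("p" * 26, "g", 0, 1)]), policy="max")


class TestTopTargetSet:
    def test_prefix_reaching_coverage(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "fraction_of_targeting": [0.5, 0.3, 0.2]}
        )
        assert top_target_set(table, 0.7) == ["a", "b"]
        assert top_target_set(table, 1.0) == ["a", "b", "c"]
        assert top_target_set(table, 0.5) == ["a"]

    def test_coverage_validated(self):
        table = pd.DataFrame({"gene_id": ["a"], "fraction_of_targeting": [1.0]})
        with pytest.raises(ValueError):
            top_target_set(table, 0.0)


def feature_transcript(rng, utr5=40, cds=100, utr3=60):
    n = utr5 + cds + utr3
    genome = Genome({"chr": random_dna(rng, n)})
    gene = GeneModel("g1", "chr", "+", [(0, n)], cds_span=(utr5, utr5 + cds))
    return build_transcript(gene, genome)


class TestMetagene:
    def test_all_sites_at_first_base_of_3utr(self, rng):
        tr = feature_transcript(rng)
        pos_3utr = 140  # first base of the 3' UTR
        t = site_rows([(f"p{i}" + "A" * 24, "g1", pos_3utr - 19, 1) for i in range(5)])
        prof = metagene_profile(t, {"g1": tr}, ["g1"])
        hot = prof[(prof["feature"] == "3UTR") & (prof["bin"] == 1)]
        assert hot["mean_fraction"].iloc[0] == 1.0
        assert np.isclose(prof["mean_fraction"].sum(), 1.0)

    def test_binning_matches_bruteforce_oracle(self, rng):
        """Uniformly placed 5' ends agree with an independent binning."""
        tr = feature_transcript(rng, utr5=40, cds=100, utr3=60)
        n_bins = 20
        rows = []
        ends = range(20, 200)
        for i, end in enumerate(ends):
            rows.append((f"p{i:03d}" + "A" * 20, "g1", end - 20, 1))
        t = site_rows(rows)
        prof = metagene_profile(t, {"g1": tr}, ["g1"], n_bins=n_bins)
        # oracle: direct histogram over feature-relative offsets
        starts = {"5UTR": 0, "CDS": 40, "3UTR": 140}
        lengths = {"5UTR": 40, "CDS": 100, "3UTR": 60}
        expected = {(f, b): 0.0 for f in starts for b in range(n_bins)}
        for end in ends:
            pos = end - 1
            f = "5UTR" if pos < 40 else "CDS" if pos < 140 else "3UTR"
            b = min(n_bins * (pos - starts[f]) // lengths[f], n_bins - 1)
            expected[(f, b)] += 1
        total = sum(expected.values())
        for row in prof.itertuples():
            assert row.mean_fraction == pytest.approx(
                expected[(row.feature, row.bin - 1)] / total
            )

    def test_gene_without_utr_excluded(self, rng):
        tr_ok = feature_transcript(rng)
        genome = Genome({"chr": random_dna(rng, 100)})
        no_utr = build_transcript(
            GeneModel("g2", "chr", "+", [(0, 100)], cds_span=(0, 100)), genome
        )
        t = site_rows([("p" * 26, "g1", 121, 1), ("q" * 26, "g2", 10, 1)])
        prof = metagene_profile(t, {"g1": tr_ok, "g2": no_utr}, ["g1", "g2"])
        assert np.isclose(prof["mean_fraction"].sum(), 1.0)


class TestMoleculesPerCell:
    def test_headline_arithmetic(self):
        assert molecules_per_cell(0.016, 1e7) == 160_000
        assert molecules_per_cell(0.12, 160_000, round_thousand=True) == 19_000

    def test_zero_and_bounds(self):
        assert molecules_per_cell(0.0) == 0
        with pytest.raises(ValueError):
            molecules_per_cell(-0.1)
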