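"""Target ranking, top-target sets, metagene profiles and abundance scaling.

A gene's rank reflects how much of the mRNA-targeting piRNA pool
converges on it.  By default weights are read counts (abundance
weighting); ``unique=True`` switches to counting distinct piRNA
sequences instead.  A piRNA that targets several genes has its weight
divided equally between them under the default ``split`` policy, so the
per-gene fractions remain proportions of the targeting pool; the
``full`` policy credits full weight to every targeted gene and
renormalises afterwards.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import CDS, UTR3, UTR5, PiRNAPool, TranscriptSeq, merge_intervals
from .matching import SiteTable

logger = logging.getLogger(__name__)

FEATURES = (UTR5, CDS, UTR3)


def targeting_fraction(pool: PiRNAPool, site_table: SiteTable, unique: bool = False) -> float:
    """Fraction of the pool (by reads, or unique sequences) with >= 1 site."""
    if pool.total_reads == 0:
        raise ValueError("empty pool")
    targeting = set(site_table.df["pirna"])
    if unique:
        return sum(1 for s, _ in pool.records if s in targeting) / len(pool.records)
    w = sum(c for s, c in pool.records if s in targeting)
    return w / pool.total_reads


def aggregate_by_gene(
    site_table: SiteTable, policy: str = "split", unique: bool = False
) -> pd.DataFrame:
    """Rank genes by converging piRNA weight.

    Returns a DataFrame with columns ``gene_id, targeting_weight,
    fraction_of_targeting, rank, span_nt, n_unique_pirnas``, sorted by
    rank.  Ties in fraction break lexicographically by gene_id.
    """
    if policy not in ("split", "full"):
        raise ValueError(f"unknown policy {policy!r}")
    df = site_table.df
    if df.empty:
        raise ValueError("empty site table")

    per_pair = df.drop_duplicates(["pirna", "gene_id"])[["pirna", "gene_id", "count"]]
    weight = per_pair["count"].astype(float)
    if unique:
        weight = pd.Series(1.0, index=per_pair.index)
    if policy == "split":
        n_genes = per_pair.groupby("pirna")["gene_id"].transform("size")
        weight = weight / n_genes
    contrib = per_pair.assign(w=weight).groupby("gene_id")["w"].sum()

    spans = {}
    for gid, grp in df.groupby("gene_id"):
        ivals = merge_intervals(
            list(zip(grp["start"].astype(int), grp["end"].astype(int)))
        )
        spans[gid] = sum(e - s for s, e in ivals)
    n_unique = df.groupby("gene_id")["pirna"].nunique()

    table = pd.DataFrame(
        {
            "gene_id": contrib.index,
            "targeting_weight": contrib.values,
            "fraction_of_targeting": contrib.values / contrib.values.sum(),
            "span_nt": [spans[g] for g in contrib.index],
            "n_unique_pirnas": [int(n_unique[g]) for g in contrib.index],
        }
    )
    table = table.sort_values(
        ["fraction_of_targeting", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[
        ["gene_id", "targeting_weight", "fraction_of_targeting", "rank",
         "span_nt", "n_unique_pirnas"]
    ]


def top_target_set(rank_table: pd.DataFrame, coverage: float = 0.70) -> list[str]:
    """Smallest rank prefix whose cumulative fraction reaches ``coverage``."""
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    cum = rank_table["fraction_of_targeting"].cumsum()
    n = int(np.searchsorted(cum.values, coverage - 1e-12) + 1)
    n = min(n, len(rank_table))
    return rank_table["gene_id"].iloc[:n].tolist()


def metagene_profile(
    site_table: SiteTable,
    transcripts: dict[str, TranscriptSeq],
    genes: list[str] | None = None,
    n_bins: int = 20,
    weighted: bool = True,
) -> pd.DataFrame:
    """Mean binned distribution of piRNA 5'-end positions across features.

    Each selected gene's sites are placed at the transcript coordinate
    paired to the piRNA 5' end (``end - 1`` of the site interval, since
    the piRNA is antisense), assigned to the feature of that base and to
    bin ``floor(n_bins * offset_within_feature / feature_length)``.  The
    per-gene 3 x n_bins vector is normalised to sum 1, then averaged
    over genes.  Genes lacking any of 5UTR/CDS/3UTR are excluded with a
    log entry.

    Returns a DataFrame with columns ``feature, bin, mean_fraction``
    (features ordered 5UTR, CDS, 3UTR; bins 1-based).
    """
    df = site_table.df
    if genes is None:
        genes = sorted(df["gene_id"].unique())
    per_gene = []
    for gid in genes:
        tr = transcripts[gid]
        flen = tr.feature_lengths()
        if any(flen.get(f, 0) == 0 for f in FEATURES):
            logger.info("metagene: %s lacks a transcript feature, excluded", gid)
            continue
        sub = df[df["gene_id"] == gid]
        if sub.empty:
            continue
        starts = {f: int(np.flatnonzero(tr.feature_map == f)[0]) for f in FEATURES}
        vec = np.zeros((3, n_bins))
        w = sub["count"].to_numpy(float) if weighted else np.ones(len(sub))
        for (end, wt) in zip(sub["end"].astype(int), w):
            pos = end - 1
            if pos >= len(tr):
                continue
            feat = tr.feature_map[pos]
            if feat not in FEATURES:
                continue
            fi = FEATURES.index(feat)
            off = pos - starts[feat]
            b = min(int(n_bins * off / flen[feat]), n_bins - 1)
            vec[fi, b] += wt
        total = vec.sum()
        if total > 0:
            per_gene.append(vec / total)
    if not per_gene:
        raise ValueError("no genes with sites and complete feature annotation")
    mean = np.mean(per_gene, axis=0)
    rows = [
        {"feature": f, "bin": b + 1, "mean_fraction": mean[fi, b]}
        for fi, f in enumerate(FEATURES)
        for b in range(n_bins)
    ]
    return pd.DataFrame(rows)


def molecules_per_cell(
    fraction: float, total_per_cell: float = 1e7, round_thousand: bool = False
) -> float:
    """Scale a pool fraction to absolute molecules per cell.

    The default total of 1e7 piRNA molecules per spermatocyte turns a
    1.6% mRNA-targeting fraction into 160,000 targeting molecules.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be within [0, 1]")
    n = fraction * total_per_cell
    if round_thousand:
        # bankers-free rounding: nearest thousand, half away from zero
        return math.floor(n / 1000 + 0.5) * 1000
    return n
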