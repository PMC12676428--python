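"""Targeting-group expression comparisons.

Differential-expression estimates are consumed, never computed here:
any gene-level table of log2 fold changes (e.g. DESeq2 output) can be
compared across targeting groups.  Genes are partitioned into top
targets (the cumulative-coverage prefix of the ranking), lower-ranked
targets, and non-targets, and their fold-change distributions compared
with a two-sample Kolmogorov-Smirnov test.  Upregulation of top
targets upon loss of the piRNA effector is the expected signal of
direct piRNA-mediated repression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .convergence import top_target_set

logger = logging.getLogger(__name__)

TOP, LOWER, NON = "top_targets", "lower_targets", "non_targets"


def load_expression_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-level expression table (gene_id, log2fc[, padj])."""
    required = {"gene_id", "log2fc"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in expression table")
    return df.reset_index(drop=True)


def assign_groups(
    rank_table: pd.DataFrame,
    expression_table: pd.DataFrame,
    coverage: float = 0.70,
) -> pd.DataFrame:
    """Partition expressed genes by targeting rank.

    top_targets: the cumulative-coverage prefix of the ranking that is
    present in the expression table; lower_targets: remaining targeted
    genes; non_targets: expressed genes with zero targeting weight.
    Returns ``gene_id, group`` (one row per expressed gene).
    """
    expression_table = load_expression_table(expression_table)
    expressed = set(expression_table["gene_id"])
    top = set(top_target_set(rank_table, coverage))
    targeted = set(rank_table["gene_id"])
    if not expressed & targeted:
        raise ValueError("expression table shares no genes with the ranking")
    groups = [
        TOP if g in top else LOWER if g in targeted else NON
        for g in expression_table["gene_id"]
    ]
    return pd.DataFrame({"gene_id": expression_table["gene_id"], "group": groups})


def ecdf(values: np.ndarray):
    """Empirical CDF as a right-continuous step function F(x)."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty sample")
    n = values.size

    def f(x):
        return np.searchsorted(values, x, side="right") / n

    return f


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (two-sided, asymptotic p).

    D is the exact supremum of |ECDF_a - ECDF_b|, evaluated by merging
    the sorted samples (the supremum over jump points covers both
    one-sided deviations, so ties are handled correctly).  The p-value
    uses the Kolmogorov distribution at the effective sample size
    n1*n2/(n1+n2); below 8 observations per sample the asymptotic
    approximation is poor and a warning is emitted.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    if min(n1, n2) < 8:
        warnings.warn(
            "asymptotic KS p-value unreliable below 8 observations per sample",
            stacklevel=2,
        )
    pooled = np.concatenate([a, b])
    cdf1 = np.searchsorted(a, pooled, side="right") / n1
    cdf2 = np.searchsorted(b, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    en = n1 * n2 / (n1 + n2)
    p = float(stats.kstwo.sf(d, int(round(en))))
    p = float(np.clip(p, 0.0, 1.0))
    return KSResult(statistic=d, p_value=p, n1=n1, n2=n2)


def compare_groups(
    expression_table: pd.DataFrame, groups: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise KS comparisons between targeting groups.

    Returns one row per group pair with D, p and sample sizes; the
    qualitative expectation under piRNA-mediated repression is that the
    top-vs-non comparison dominates the lower-vs-non one.
    """
    expression_table = load_expression_table(expression_table)
    merged = expression_table.merge(groups, on="gene_id")
    samples = {
        name: grp["log2fc"].to_numpy(float)
        for name, grp in merged.groupby("group")
    }
    rows = []
    for g1, g2 in ((TOP, NON), (LOWER, NON), (TOP, LOWER)):
        if g1 not in samples or g2 not in samples:
            continue
        res = ks_two_sample(samples[g1], samples[g2])
        rows.append(
            {
                "group_a": g1,
                "group_b": g2,
                "D": res.statistic,
                "p_value": res.p_value,
                "n_a": res.n1,
                "n_b": res.n2,
                "median_shift": float(
                    np.median(samples[g1]) - np.median(samples[g2])
                ),
            }
        )
    return pd.DataFrame(rows)
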