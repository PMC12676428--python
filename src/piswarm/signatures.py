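"""Nucleotide-composition and ping-pong signatures.

Primary piRNA biogenesis leaves a uridine preference at position 1
(1U); slicer-driven ping-pong amplification additionally enriches
adenosine at position 10 (10A) and produces opposite-strand piRNA
pairs whose 5' ends overlap by exactly 10 nt.  These two read-outs
together distinguish primary from amplified piRNA populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PiRNAPool
from .attribution import GenomicHit

ALPHABET = ("A", "C", "G", "U")


@dataclass
class PositionFrequencyMatrix:
    """Read-count-weighted base frequencies per piRNA position (1-based).

    Ragged normalisation: position p's denominator counts only records
    of length >= p, so mixed-length pools give well-defined logos.
    """

    freqs: pd.DataFrame   # index 1..L, columns A/C/G/U
    n_effective: float

    @property
    def u1_fraction(self) -> float:
        return float(self.freqs.loc[1, "U"])

    @property
    def a10_fraction(self) -> float:
        return float(self.freqs.loc[10, "A"])


def position_frequencies(
    pool: PiRNAPool, weighted: bool = True
) -> PositionFrequencyMatrix:
    """Per-position base composition of a pool (T read as U)."""
    if not pool.records or pool.total_reads == 0:
        raise ValueError("empty pool")
    max_len = max(len(s) for s, _ in pool.records)
    counts = np.zeros((max_len, 4))
    for seq, c in pool.records:
        w = float(c) if weighted else 1.0
        rna = seq.replace("T", "U")
        for i, base in enumerate(rna):
            if base in ALPHABET:
                counts[i, ALPHABET.index(base)] += w
    denom = counts.sum(axis=1, keepdims=True)
    denom[denom == 0] = np.nan
    freqs = pd.DataFrame(
        counts / denom, index=np.arange(1, max_len + 1), columns=list(ALPHABET)
    )
    n_eff = float(pool.total_reads if weighted else len(pool.records))
    return PositionFrequencyMatrix(freqs=freqs, n_effective=n_eff)


@dataclass
class PingPongProfile:
    """5'-overlap co-occurrence weights for offsets 1..max_offset.

    ``weights[o]`` accumulates, over all opposite-strand hit pairs on
    the same chromosome whose 5' ends overlap by exactly o nt, the
    product of the two hits' weights (read count x genomic weight
    share).  ``z10`` is the z-score of offset 10 against the other
    offsets; it is None when fewer than 2 offsets carry data.
    """

    weights: pd.Series  # index 1..max_offset
    z10: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.weights.index, "weight": self.weights.values}
        )


def ping_pong_overlap(
    hits: list[GenomicHit],
    counts: dict[str, int] | None = None,
    max_offset: int = 20,
) -> PingPongProfile:
    """Ping-pong 5'-overlap profile of a set of genomic hits.

    Two reads on opposite strands with 5' ends at plus-strand
    coordinate ``a`` and minus-strand coordinate ``b`` overlap by
    ``b - a + 1`` nt.  A 10-nt overlap is the ping-pong signature
    (guide nt 1 opposite the base paired to partner nt 10).
    """
    plus: dict[str, dict[int, float]] = {}
    minus: dict[str, dict[int, float]] = {}
    for h in hits:
        w = h.weight_share * (counts.get(h.pirna, 1) if counts else 1)
        side = plus if h.strand == "+" else minus
        d = side.setdefault(h.chrom, {})
        pos = h.five_prime_pos
        d[pos] = d.get(pos, 0.0) + w

    weights = np.zeros(max_offset)
    for chrom, pdict in plus.items():
        mdict = minus.get(chrom)
        if not mdict:
            continue
        for a, wa in pdict.items():
            for o in range(1, max_offset + 1):
                wb = mdict.get(a + o - 1)
                if wb:
                    weights[o - 1] += wa * wb

    series = pd.Series(weights, index=np.arange(1, max_offset + 1))
    n_nonzero = int((series > 0).sum())
    z10 = None
    if n_nonzero >= 2 and 10 <= max_offset:
        others = series.drop(10)
        sd = others.std(ddof=1)
        if sd > 0:
            z10 = float((series.loc[10] - others.mean()) / sd)
    return PingPongProfile(weights=series, z10=z10)
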