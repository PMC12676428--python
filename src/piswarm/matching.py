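"""Antisense piRNA -> mRNA target matching.

A piRNA is scored against an mRNA through a fixed guide window,
by default nucleotides 2-21 counted 1-based from the piRNA 5' end.
The reverse complement of that 20-mer is compared, ungapped, to every
transcript substring; positions with at most ``max_mismatches``
Hamming mismatches (default 1) are target sites.  Position 1 and any
3' tail beyond the window are never evaluated, so a mismatch opposite
piRNA nt 1 is free.  G:U wobble is counted as a mismatch: the rule is a
pure mismatch count over a fixed window, which implies strict
Watson-Crick comparison.

Matching runs against the mRNA sense sequence only — a piRNA matching
the mRNA in sense orientation is not a target site.

The production matcher is a pigeonhole seed index: the window is split
into ``max_mismatches + 1`` seeds, so every admissible site contains at
least one exact seed and is recovered via an exact k-mer hit plus
Hamming verification.  ``find_sites_bruteforce`` is the reference the
index is proven equivalent to in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import PiRNAPool, TranscriptSeq, revcomp

logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "pirna",
    "gene_id",
    "start",
    "end",
    "mismatch_count",
    "mismatch_positions",
    "slice_pos",
    "count",
]


@dataclass(frozen=True)
class MatchParams:
    """Guide-window matching rule (positions 1-based from the 5' end)."""

    window_start: int = 2
    window_end: int = 21
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.window_start <= self.window_end):
            raise ValueError("require 1 <= window_start <= window_end")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start + 1


@dataclass(frozen=True)
class TargetSite:
    """One piRNA/mRNA antisense match.

    ``start:end`` is the transcript interval (0-based half-open) paired
    to piRNA nt ``window_start..window_end``; because the piRNA lies
    antisense, transcript position ``end - 1`` pairs with the window's
    5'-most evaluated nucleotide.  ``slice_pos`` is the transcript
    coordinate of the base paired to piRNA nt 10, i.e. immediately 3'
    of the scissile phosphate under slicer cleavage between target
    positions opposite guide nt 10 and 11.
    """

    pirna: str
    gene_id: str
    start: int
    end: int
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    slice_pos: int


def antisense_window(pirna: str, params: MatchParams = MatchParams()) -> str:
    """Reverse complement of piRNA positions window_start..window_end.

    The returned string is compared directly to the mRNA sense strand.
    Raises ValueError for piRNAs shorter than the window end; callers
    that stream pools use :func:`match_pool`, which excludes and logs
    such records instead.
    """
    if len(pirna) < params.window_end:
        raise ValueError(
            f"piRNA of length {len(pirna)} shorter than window end "
            f"{params.window_end}"
        )
    return revcomp(pirna[params.window_start - 1: params.window_end])


def _mismatch_positions(
    window: str, segment: str, params: MatchParams
) -> tuple[int, ...] | None:
    """piRNA-coordinate mismatch positions, or None if over budget.

    Window index i (0-based, on the transcript) pairs with piRNA
    nt ``window_end - i``.  Genome N never matches any base.
    """
    budget = params.max_mismatches
    hits = []
    for i, (w, t) in enumerate(zip(window, segment)):
        if w != t or w == "N":
            if not budget:
                return None
            budget -= 1
            hits.append(params.window_end - i)
    return tuple(sorted(hits))


def _make_site(
    pirna: str, gene_id: str, start: int, mm: tuple[int, ...], params: MatchParams
) -> TargetSite:
    return TargetSite(
        pirna=pirna,
        gene_id=gene_id,
        start=start,
        end=start + params.window_length,
        mismatch_count=len(mm),
        mismatch_positions=mm,
        slice_pos=start + params.window_end - 10,
    )


def find_sites_bruteforce(
    pirna: str, transcript: TranscriptSeq, params: MatchParams = MatchParams()
) -> list[TargetSite]:
    """Every admissible antisense site of one piRNA on one transcript."""
    window = antisense_window(pirna, params)
    w = params.window_length
    seq = transcript.sequence
    sites = []
    for start in range(len(seq) - w + 1):
        mm = _mismatch_positions(window, seq[start: start + w], params)
        if mm is not None:
            sites.append(_make_site(pirna, transcript.gene_id, start, mm, params))
    return sites


# ---------------------------------------------------------------------------
# Seed index
# ---------------------------------------------------------------------------

def _seed_spans(window_length: int, n_seeds: int) -> list[tuple[int, int]]:
    """Split the window into n_seeds contiguous pieces, last one longest."""
    base = window_length // n_seeds
    spans = []
    pos = 0
    for i in range(n_seeds):
        length = base if i < n_seeds - 1 else window_length - base * (n_seeds - 1)
        spans.append((pos, pos + length))
        pos += length
    return spans


class SeedIndex:
    """Exact k-mer index over transcripts for pigeonhole candidate lookup.

    With ``m = max_mismatches`` the window splits into ``m + 1`` seeds;
    any site with <= m mismatches leaves at least one seed exact, so
    looking up every seed and verifying the full window recovers the
    brute-force site set.
    """

    def __init__(
        self,
        transcripts: dict[str, TranscriptSeq],
        params: MatchParams = MatchParams(),
    ):
        self.params = params
        self.transcripts = transcripts
        self.gene_ids = sorted(transcripts)
        self.spans = _seed_spans(params.window_length, params.max_mismatches + 1)
        # one dict per seed slot: kmer -> list of (gene_idx, window_start)
        self._tables: list[dict[str, list[tuple[int, int]]]] = []
        w = params.window_length
        for s_lo, s_hi in self.spans:
            k = s_hi - s_lo
            table: dict[str, list[tuple[int, int]]] = {}
            for gi, gid in enumerate(self.gene_ids):
                seq = transcripts[gid].sequence
                for start in range(len(seq) - w + 1):
                    kmer = seq[start + s_lo: start + s_hi]
                    table.setdefault(kmer, []).append((gi, start))
            self._tables.append(table)

    def find_sites(self, pirna: str) -> list[TargetSite]:
        params = self.params
        window = antisense_window(pirna, params)
        w = params.window_length
        seen: set[tuple[int, int]] = set()
        sites: list[TargetSite] = []
        for (s_lo, s_hi), table in zip(self.spans, self._tables):
            for gi, start in table.get(window[s_lo:s_hi], ()):
                key = (gi, start)
                if key in seen:
                    continue
                seen.add(key)
                gid = self.gene_ids[gi]
                seq = self.transcripts[gid].sequence
                mm = _mismatch_positions(window, seq[start: start + w], params)
                if mm is not None:
                    sites.append(_make_site(pirna, gid, start, mm, params))
        sites.sort(key=lambda s: (s.gene_id, s.start))
        return sites


def build_seed_index(
    transcripts: dict[str, TranscriptSeq], params: MatchParams = MatchParams()
) -> SeedIndex:
    return SeedIndex(transcripts, params)


# ---------------------------------------------------------------------------
# Pool-level matching
# ---------------------------------------------------------------------------

class SiteTable:
    """All target sites of a pool, one row per (piRNA, gene, site start).

    Wraps a DataFrame with columns ``pirna, gene_id, start, end,
    mismatch_count, mismatch_positions, slice_pos, count`` where count
    is the piRNA's read count in the pool.
    """

    def __init__(self, df: pd.DataFrame, n_too_short: int = 0):
        self.df = df.reset_index(drop=True)
        self.n_too_short = n_too_short

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "SiteTable":
        return cls(pd.DataFrame(columns=SITE_COLUMNS))

    @classmethod
    def from_sites(
        cls, sites: list[TargetSite], counts: dict[str, int], n_too_short: int = 0
    ) -> "SiteTable":
        rows = [
            {
                "pirna": s.pirna,
                "gene_id": s.gene_id,
                "start": s.start,
                "end": s.end,
                "mismatch_count": s.mismatch_count,
                "mismatch_positions": ",".join(map(str, s.mismatch_positions)),
                "slice_pos": s.slice_pos,
                "count": counts[s.pirna],
            }
            for s in sites
        ]
        df = pd.DataFrame(rows, columns=SITE_COLUMNS)
        df = df.sort_values(["gene_id", "start", "pirna"], kind="mergesort")
        return cls(df, n_too_short)

    def targeting_sequences(self) -> list[str]:
        return sorted(self.df["pirna"].unique())

    def site_key_set(self) -> set[tuple[str, str, int]]:
        return set(
            zip(self.df["pirna"], self.df["gene_id"], self.df["start"].astype(int))
        )


def match_pool(
    pool: PiRNAPool,
    index: SeedIndex,
    params: MatchParams | None = None,
) -> SiteTable:
    """Match every pool record through the seed index.

    piRNAs shorter than the window end cannot be evaluated; they are
    excluded and counted in ``SiteTable.n_too_short``.
    """
    if params is not None and params != index.params:
        raise ValueError("params must match the index's params")
    counts = pool.counts()
    too_short = 0
    sites: list[TargetSite] = []
    for seq, _count in pool.records:
        if len(seq) < index.params.window_end:
            too_short += 1
            continue
        sites.extend(index.find_sites(seq))
    if too_short:
        logger.info("match_pool: %d pool records shorter than window", too_short)
    return SiteTable.from_sites(sites, counts, n_too_short=too_short)


def match_pool_bruteforce(
    pool: PiRNAPool,
    transcripts: dict[str, TranscriptSeq],
    params: MatchParams = MatchParams(),
) -> SiteTable:
    """Brute-force counterpart of :func:`match_pool` (oracle path)."""
    counts = pool.counts()
    too_short = 0
    sites: list[TargetSite] = []
    for seq, _count in pool.records:
        if len(seq) < params.window_end:
            too_short += 1
            continue
        for gid in sorted(transcripts):
            sites.extend(find_sites_bruteforce(seq, transcripts[gid], params))
    return SiteTable.from_sites(sites, counts, n_too_short=too_short)
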