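"""Pseudogene-fragment discovery inside piRNA clusters.

A pseudogene fragment (PGF) is a retrotransposed mRNA copy embedded in
a cluster.  In antisense orientation relative to the cluster's
precursor strand it supplies extensive complementary sequence, i.e. the
template for an mRNA-targeting piRNA swarm.  This module finds PGFs by
Smith-Waterman local alignment of cluster sequence against the
transcriptome, chains collinear sub-alignments (so a retained intron
shows up as a cluster-side insertion between chained exon blocks),
classifies the insertion anatomy (5' truncation, processed vs partly
processed state) and detects the target-site duplications (TSDs) that
flank LINE-mediated integration events.

Alignment scoring: match +2, mismatch -3; a gap of length L costs
``|gap_open| + (L-1)*|gap_extend|`` (first gapped column opens the
gap).  The dynamic programme itself is `biotite`'s banded-free optimal
local aligner; an independent quadratic Gotoh reference in the test
suite pins down the exact scoring semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .io import ClusterAnnotation, GeneModel, Genome, TranscriptSeq, revcomp

logger = logging.getLogger(__name__)

SENSE, ANTISENSE = "sense", "antisense"
PROCESSED, PARTLY_PROCESSED = "processed", "partly_processed"


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


def _substitution_matrix(scoring: Scoring) -> balign.SubstitutionMatrix:
    """ACGT(+ambiguity) matrix: exact unambiguous match scores ``match``,
    everything else (including N vs anything) scores ``mismatch``."""
    alph = bseq.NucleotideSequence.alphabet_amb
    n = len(alph)
    mat = np.full((n, n), scoring.mismatch, dtype=np.int32)
    for b in "ACGT":
        i = alph.encode(b)
        mat[i, i] = scoring.match
    return balign.SubstitutionMatrix(alph, alph, mat)


@dataclass
class LocalAlignment:
    """One gapped local alignment block.

    Coordinates are 0-based half-open on the *oriented* query handed to
    the aligner and on the subject.  ``trace`` is a (columns, 2) array
    of (query pos, subject pos) with -1 marking gaps, matching the
    orientation of the interval fields.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int
    n_matches: int
    n_columns: int
    strand_relation: str = SENSE
    trace: np.ndarray = field(default=None, repr=False)

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.n_matches / self.n_columns

    def subject_columns(self) -> np.ndarray:
        return self.trace[self.trace[:, 1] >= 0, 1]


def _align_once(
    query: str, subject: str, scoring: Scoring
) -> LocalAlignment | None:
    """Best local alignment of query vs subject (None if score <= 0)."""
    if not query or not subject:
        raise ValueError("cannot align empty sequence")
    q = bseq.NucleotideSequence(query, ambiguous=True)
    s = bseq.NucleotideSequence(subject, ambiguous=True)
    mat = _substitution_matrix(scoring)
    alns = balign.align_optimal(
        q, s, mat,
        gap_penalty=(scoring.gap_open, scoring.gap_extend),
        local=True,
        max_number=1,
    )
    if not alns or alns[0].score <= 0:
        return None
    aln = alns[0]
    trace = aln.trace
    qcols = trace[:, 0]
    scols = trace[:, 1]
    both = (qcols >= 0) & (scols >= 0)
    matches = int(
        np.sum(
            np.frombuffer(query.encode(), dtype="S1")[qcols[both]]
            == np.frombuffer(subject.encode(), dtype="S1")[scols[both]]
        )
    )
    return LocalAlignment(
        q_start=int(qcols[qcols >= 0].min()),
        q_end=int(qcols[qcols >= 0].max()) + 1,
        s_start=int(scols[scols >= 0].min()),
        s_end=int(scols[scols >= 0].max()) + 1,
        score=int(aln.score),
        n_matches=matches,
        n_columns=int(trace.shape[0]),
        trace=trace,
    )


def local_align_blocks(
    query: str,
    subject: str,
    scoring: Scoring = Scoring(),
    min_score: int = 40,
    min_query_segment: int = 20,
) -> list[LocalAlignment]:
    """Greedy non-overlapping (on the query) local alignments.

    The optimal alignment is reported first; the query is then split at
    its footprint and each remaining segment re-aligned, until no
    segment scores above ``min_score``.  Deterministic.
    """
    results: list[LocalAlignment] = []
    stack: list[tuple[int, int]] = [(0, len(query))]
    while stack:
        qlo, qhi = stack.pop()
        if qhi - qlo < min_query_segment:
            continue
        aln = _align_once(query[qlo:qhi], subject, scoring)
        if aln is None or aln.score < min_score:
            continue
        shifted_trace = aln.trace.copy()
        shifted_trace[shifted_trace[:, 0] >= 0, 0] += qlo
        results.append(
            LocalAlignment(
                q_start=aln.q_start + qlo,
                q_end=aln.q_end + qlo,
                s_start=aln.s_start,
                s_end=aln.s_end,
                score=aln.score,
                n_matches=aln.n_matches,
                n_columns=aln.n_columns,
                trace=shifted_trace,
            )
        )
        stack.append((qlo, aln.q_start + qlo))
        stack.append((aln.q_end + qlo, qhi))
    results.sort(key=lambda a: a.q_start)
    return results


def local_align(
    a: str, b: str, scoring: Scoring = Scoring(), min_score: int = 40
) -> list[LocalAlignment]:
    """Local alignments of ``a`` vs ``b`` trying both orientations of ``a``.

    Antisense blocks carry query coordinates on the *forward* strand of
    ``a`` (interval of the aligned region, trace left in oriented
    coordinates).  Blocks are sorted by descending score.
    """
    out = []
    for orient, query in ((SENSE, a), (ANTISENSE, revcomp(a))):
        for blk in local_align_blocks(query, b, scoring, min_score):
            if orient == ANTISENSE:
                q_start = len(a) - blk.q_end
                q_end = len(a) - blk.q_start
                blk = LocalAlignment(
                    q_start=q_start,
                    q_end=q_end,
                    s_start=blk.s_start,
                    s_end=blk.s_end,
                    score=blk.score,
                    n_matches=blk.n_matches,
                    n_columns=blk.n_columns,
                    strand_relation=ANTISENSE,
                    trace=blk.trace,
                )
            else:
                blk.strand_relation = SENSE
            out.append(blk)
    out.sort(key=lambda x: (-x.score, x.q_start))
    return out


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def chain_blocks(
    blocks: list[LocalAlignment],
    max_gap: int = 5000,
    subject_overlap_slack: int = 10,
) -> list[list[LocalAlignment]]:
    """Partition collinear blocks into chains (ascending q and s).

    Greedy left-to-right in query order: a block joins the current
    chain if its subject interval continues (start >= previous end -
    slack) within ``max_gap`` on both axes; otherwise it starts a new
    chain.
    """
    chains: list[list[LocalAlignment]] = []
    for blk in sorted(blocks, key=lambda a: a.q_start):
        placed = False
        for chain in chains:
            prev = chain[-1]
            if (
                blk.q_start >= prev.q_end
                and blk.s_start >= prev.s_end - subject_overlap_slack
                and blk.q_start - prev.q_end <= max_gap
                and blk.s_start - prev.s_end <= max_gap
            ):
                chain.append(blk)
                placed = True
                break
        if not placed:
            chains.append([blk])
    return chains


# ---------------------------------------------------------------------------
# PGF scan
# ---------------------------------------------------------------------------

@dataclass
class PGFHit:
    """A pseudogene fragment call inside a cluster."""

    cluster_id: str
    chrom: str
    genomic_interval: tuple[int, int]
    target_gene_id: str
    mrna_interval: tuple[int, int]
    strand_relation: str                # antisense PGFs template targeting piRNAs
    percent_identity: float
    exons_covered: list[int]
    five_prime_truncated: bool
    processed_state: str                # processed | partly_processed
    aligned_columns: int
    score: int
    retained_introns: list[int] = field(default_factory=list)


def _relation(strand_mode: str, aligned_revcomp: bool) -> str:
    """Orientation of piRNAs relative to the mRNA.

    ``aligned_revcomp`` is True when the reverse complement of the
    cluster plus strand aligned to the mRNA.  For a plus-strand
    precursor that means the precursor carries mRNA-complementary
    sequence, so its piRNAs are antisense to the target.  A
    bidirectional cluster produces piRNAs from both strands, so either
    alignment orientation yields antisense piRNAs.
    """
    if strand_mode == "bidirectional":
        return ANTISENSE
    if strand_mode == "plus":
        return ANTISENSE if aligned_revcomp else SENSE
    return SENSE if aligned_revcomp else ANTISENSE


def _intron_sequences(gene: GeneModel, genome: Genome) -> list[str]:
    """Introns in mRNA-sense orientation, ordered by mRNA position."""
    seqs = [genome.fetch(gene.chrom, s, e, gene.strand) for s, e in gene.introns()]
    if gene.strand == "-":
        seqs = seqs[::-1]
    return seqs


def _gap_runs(trace: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Query intervals of subject-gap runs (query-only columns) >= min_run."""
    runs = []
    run_start = None
    prev_q = None
    for q, s in trace:
        if s < 0 and q >= 0:
            if run_start is None:
                run_start = q
            prev_q = q
        else:
            if run_start is not None and prev_q - run_start + 1 >= min_run:
                runs.append((int(run_start), int(prev_q) + 1))
            run_start = None
    if run_start is not None and prev_q - run_start + 1 >= min_run:
        runs.append((int(run_start), int(prev_q) + 1))
    return runs


def _insertion_is_intronic(
    insert_seq: str,
    intron_seqs: list[str],
    scoring: Scoring,
    min_identity: float = 80.0,
) -> int | None:
    """Index (1-based, mRNA order) of the intron the insertion matches."""
    if len(insert_seq) < 20:
        return None
    for i, intron in enumerate(intron_seqs, 1):
        if not intron:
            continue
        aln = _align_once(insert_seq, intron, scoring)
        if aln is None:
            continue
        if (
            aln.percent_identity >= min_identity
            and aln.n_columns >= 0.5 * min(len(insert_seq), len(intron))
        ):
            return i
    return None


def scan_pgf(
    cluster: ClusterAnnotation,
    genome: Genome,
    transcripts: dict[str, TranscriptSeq],
    gene_models: dict[str, GeneModel],
    min_len: int = 100,
    min_identity: float = 80.0,
    scoring: Scoring = Scoring(),
    min_block_score: int = 60,
    truncation_threshold: int = 50,
    min_intron_insertion: int = 30,
) -> list[PGFHit]:
    """Find pseudogene fragments of any annotated gene inside a cluster.

    Chained local alignments passing ``min_len`` aligned columns and
    pooled ``min_identity`` become PGF hits.  A cluster-side insertion
    between chained blocks that matches annotated intron sequence marks
    the copy ``partly_processed``; otherwise the fragment is a clean
    splice product (``processed``).  ``five_prime_truncated`` is set
    when the alignment starts more than ``truncation_threshold`` nt
    into the transcript — the hallmark of an abortive LINE-machinery
    reverse transcription that lost the mRNA 5' end.
    """
    cseq = genome.fetch(cluster.chrom, cluster.start, cluster.end)
    L = len(cseq)
    hits: list[PGFHit] = []
    for gid in sorted(transcripts):
        tr = transcripts[gid]
        gene = gene_models[gid]
        intron_seqs = _intron_sequences(gene, genome)
        for aligned_revcomp, query in ((False, cseq), (True, revcomp(cseq))):
            blocks = local_align_blocks(
                query, tr.sequence, scoring, min_score=min_block_score
            )
            for chain in chain_blocks(blocks):
                columns = sum(b.n_columns for b in chain)
                matches = sum(b.n_matches for b in chain)
                if columns < min_len:
                    continue
                # cluster-side insertions: either a gap between chained
                # blocks, or a long query-only gap run inside one block
                # (the aligner bridges short retained introns in a
                # single alignment)
                retained = []
                intron_columns = 0
                for prev, nxt in zip(chain, chain[1:]):
                    q_gap = nxt.q_start - prev.q_end
                    s_gap = nxt.s_start - prev.s_end
                    if q_gap >= min_intron_insertion and s_gap <= 20:
                        idx = _insertion_is_intronic(
                            query[prev.q_end: nxt.q_start], intron_seqs, scoring
                        )
                        if idx is not None:
                            retained.append(idx)
                for blk in chain:
                    for run_lo, run_hi in _gap_runs(blk.trace, min_intron_insertion):
                        idx = _insertion_is_intronic(
                            query[run_lo:run_hi], intron_seqs, scoring
                        )
                        if idx is not None:
                            retained.append(idx)
                            intron_columns += run_hi - run_lo
                # a recognised retained intron aligns to intron, not
                # mRNA: drop its gap columns from the identity basis
                identity = 100.0 * matches / (columns - intron_columns)
                if identity < min_identity:
                    continue
                subject_cols = np.concatenate(
                    [b.subject_columns() for b in chain]
                )
                exons = sorted(set(tr.exon_index[subject_cols].tolist()))
                q_lo = min(b.q_start for b in chain)
                q_hi = max(b.q_end for b in chain)
                if aligned_revcomp:
                    g_lo, g_hi = cluster.start + L - q_hi, cluster.start + L - q_lo
                else:
                    g_lo, g_hi = cluster.start + q_lo, cluster.start + q_hi
                s_lo = min(b.s_start for b in chain)
                s_hi = max(b.s_end for b in chain)
                hits.append(
                    PGFHit(
                        cluster_id=cluster.cluster_id,
                        chrom=cluster.chrom,
                        genomic_interval=(g_lo, g_hi),
                        target_gene_id=gid,
                        mrna_interval=(s_lo, s_hi),
                        strand_relation=_relation(cluster.strand_mode, aligned_revcomp),
                        percent_identity=identity,
                        exons_covered=[int(e) for e in exons],
                        five_prime_truncated=s_lo > truncation_threshold,
                        processed_state=PARTLY_PROCESSED if retained else PROCESSED,
                        aligned_columns=int(columns),
                        score=int(sum(b.score for b in chain)),
                        retained_introns=retained,
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.target_gene_id, h.genomic_interval))
    return hits


# ---------------------------------------------------------------------------
# Target-site duplications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TSDResult:
    repeat_length: int
    left_copy: tuple[int, int]
    right_copy: tuple[int, int]
    offset_slack_used: int


def detect_tsd(
    genome: Genome,
    chrom: str,
    pgf_interval: tuple[int, int],
    search_window: int = 30,
    min_len: int = 8,
    boundary_slack: int = 5,
) -> TSDResult | None:
    """Longest exact direct repeat flanking a putative insertion.

    One copy must end within ``boundary_slack`` of the insertion 5'
    boundary and the other begin within ``boundary_slack`` of the 3'
    boundary; copies are at most ``search_window`` long.  Exact repeats
    only — integration-site duplications are copied verbatim by the
    staggered-nick mechanism, and allowing mismatches would make
    maximality ambiguous.  Returns None when the best repeat is shorter
    than ``min_len``.  Ties at the maximal length resolve to the copy
    pair closest to the boundaries, then leftmost.
    """
    start, end = pgf_interval
    seq = genome[chrom]
    if start - search_window - boundary_slack < 0 or end + search_window + boundary_slack > len(seq):
        raise ValueError("insufficient flanking sequence for TSD search")
    best: tuple[int, int, int] | None = None  # (slack_used, left_end, right_start)
    for k in range(search_window, min_len - 1, -1):
        candidates = []
        for left_end in range(start - boundary_slack, start + boundary_slack + 1):
            left = seq[left_end - k: left_end]
            for right_start in range(end - boundary_slack, end + boundary_slack + 1):
                if seq[right_start: right_start + k] == left:
                    slack = max(abs(left_end - start), abs(right_start - end))
                    candidates.append((slack, left_end, right_start))
        if candidates:
            slack, left_end, right_start = min(candidates)
            return TSDResult(
                repeat_length=k,
                left_copy=(left_end - k, left_end),
                right_copy=(right_start, right_start + k),
                offset_slack_used=slack,
            )
    return None


# ---------------------------------------------------------------------------
# Pairwise locus identity
# ---------------------------------------------------------------------------

def pairwise_identity(
    locus_a: str,
    locus_b: str,
    scoring: Scoring = Scoring(),
    min_block_score: int = 60,
) -> tuple[float | None, pd.DataFrame]:
    """Percent identity between two loci via chained local alignments.

    Identity is matches / aligned columns pooled over all reported
    segments in the better-scoring orientation of ``locus_a``.  When no
    segment reaches ``min_block_score`` the loci are reported as not
    comparable (identity None, empty segment table).
    """
    if not locus_a or not locus_b:
        raise ValueError("empty locus sequence")
    best_blocks: list[LocalAlignment] = []
    best_orient = SENSE
    for orient, query in ((SENSE, locus_a), (ANTISENSE, revcomp(locus_a))):
        blocks = local_align_blocks(query, locus_b, scoring, min_score=min_block_score)
        if sum(b.n_matches for b in blocks) > sum(b.n_matches for b in best_blocks):
            best_blocks, best_orient = blocks, orient
    if not best_blocks:
        return None, pd.DataFrame(
            columns=["a_start", "a_end", "b_start", "b_end", "percent_identity",
                     "orientation"]
        )
    rows = []
    for b in best_blocks:
        a_lo, a_hi = b.q_start, b.q_end
        if best_orient == ANTISENSE:
            a_lo, a_hi = len(locus_a) - b.q_end, len(locus_a) - b.q_start
        rows.append(
            {
                "a_start": a_lo,
                "a_end": a_hi,
                "b_start": b.s_start,
                "b_end": b.s_end,
                "percent_identity": b.percent_identity,
                "orientation": best_orient,
            }
        )
    identity = 100.0 * sum(b.n_matches for b in best_blocks) / sum(
        b.n_columns for b in best_blocks
    )
    return identity, pd.DataFrame(rows).sort_values("a_start").reset_index(drop=True)
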