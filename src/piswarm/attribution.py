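"""Perfect genomic mapping and source-cluster attribution.

piRNAs are traced to their loci of origin by exact full-length matching
against both genome strands ("perfect" mapping only: a piRNA is a
genome substring by biogenesis, so approximate genomic mapping is not
needed and would blur source assignment).  A piRNA occurring at k
genomic positions gets weight share 1/k at each.  Hits are assigned to
the annotated cluster containing the hit's 5'-end position (a hit
straddling a cluster edge belongs to the cluster of its 5' end), else
to NON_PIC; a targeting piRNA with no perfect hit at all is reported
under UNMAPPED and excluded from decomposition fractions by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import ClusterAnnotation, GeneModel, Genome, PiRNAPool, revcomp
from .matching import SiteTable

logger = logging.getLogger(__name__)

NON_PIC = "NON_PIC"
UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class GenomicHit:
    """One exact full-length genomic occurrence of a piRNA."""

    pirna: str
    chrom: str
    start: int          # leftmost coordinate, 0-based
    strand: str         # + / -
    weight_share: float

    @property
    def end(self) -> int:
        return self.start + len(self.pirna)

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


def map_perfect(pool: PiRNAPool, genome: Genome) -> list[GenomicHit]:
    """All exact full-length occurrences of pool sequences, both strands.

    Implemented as a single sliding scan per chromosome against a hash
    of pool sequences (forward and reverse-complemented), so runtime is
    linear in genome size times the number of distinct read lengths.
    """
    fwd: dict[str, str] = {}
    rev: dict[str, str] = {}
    lengths = set()
    for seq, _ in pool.records:
        fwd[seq] = seq
        rev[revcomp(seq)] = seq
        lengths.add(len(seq))
    lengths = sorted(lengths)

    occurrences: dict[str, list[tuple[str, int, str]]] = {s: [] for s, _ in pool.records}
    for chrom, cseq in genome.items():
        n = len(cseq)
        for i in range(n):
            for L in lengths:
                if i + L > n:
                    break
                window = cseq[i: i + L]
                hit = fwd.get(window)
                if hit is not None and len(hit) == L:
                    occurrences[hit].append((chrom, i, "+"))
                hit = rev.get(window)
                if hit is not None:
                    occurrences[hit].append((chrom, i, "-"))

    hits: list[GenomicHit] = []
    n_unmapped = 0
    for seq, occ in occurrences.items():
        if not occ:
            n_unmapped += 1
            continue
        share = 1.0 / len(occ)
        for chrom, start, strand in occ:
            hits.append(GenomicHit(seq, chrom, start, strand, share))
    if n_unmapped:
        logger.info("map_perfect: %d pool sequences unmapped", n_unmapped)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.pirna))
    return hits


def map_perfect_naive(pool: PiRNAPool, genome: Genome) -> list[GenomicHit]:
    """str.find-based reference mapper (oracle for map_perfect)."""
    occurrences: dict[str, list[tuple[str, int, str]]] = {}
    for seq, _ in pool.records:
        occ = []
        rc = revcomp(seq)
        for chrom, cseq in genome.items():
            for probe, strand in ((seq, "+"), (rc, "-")):
                i = cseq.find(probe)
                while i != -1:
                    occ.append((chrom, i, strand))
                    i = cseq.find(probe, i + 1)
        occurrences[seq] = occ
    hits = []
    for seq, occ in occurrences.items():
        if not occ:
            continue
        for chrom, start, strand in occ:
            hits.append(GenomicHit(seq, chrom, start, strand, 1.0 / len(occ)))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.pirna))
    return hits


def validate_clusters(clusters: list[ClusterAnnotation]) -> None:
    by_chrom: dict[str, list[ClusterAnnotation]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in by_chrom.items():
        cs = sorted(cs, key=lambda c: c.start)
        for a, b in zip(cs, cs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping clusters {a.cluster_id} and {b.cluster_id} "
                    f"on {chrom}"
                )


def attribute_sources(
    hits: list[GenomicHit], clusters: list[ClusterAnnotation]
) -> dict[str, dict[str, float]]:
    """Per-piRNA source weights over cluster ids and NON_PIC.

    A hit belongs to the cluster containing its 5'-end coordinate.
    Weights of one piRNA sum to 1 across sources.
    """
    validate_clusters(clusters)
    by_chrom: dict[str, list[ClusterAnnotation]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)

    def locate(chrom: str, pos: int) -> str:
        for c in by_chrom.get(chrom, ()):
            if c.start <= pos < c.end:
                return c.cluster_id
        return NON_PIC

    weights: dict[str, dict[str, float]] = {}
    for h in hits:
        label = locate(h.chrom, h.five_prime_pos)
        d = weights.setdefault(h.pirna, {})
        d[label] = d.get(label, 0.0) + h.weight_share
    return weights


@dataclass
class ClusterDecomposition:
    """Per-gene breakdown of targeting piRNA weight by source locus."""

    gene_id: str
    entries: list[tuple[str, float]]   # (source label, fraction), descending
    summary: dict[str, float]          # top/second/third/minor_lt5/non_pic
    unmapped_weight: float = 0.0       # reads excluded from the fractions

    def top_fraction(self) -> float:
        return self.summary["top"]

    def top_cluster(self) -> str | None:
        for label, _ in self.entries:
            if label != NON_PIC:
                return label
        return None


def decompose_gene(
    gene_id: str,
    site_table: SiteTable,
    source_weights: dict[str, dict[str, float]],
    minor_threshold: float = 0.05,
    include_unmapped: bool = False,
) -> ClusterDecomposition:
    """Partition a gene's targeting piRNA weight by source locus.

    The summary applies the reporting convention of cluster-origin bar
    charts: the dominant, second and third contributing clusters are
    listed individually, clusters each below ``minor_threshold`` are
    pooled as ``minor_lt5``, and non-cluster loci as ``non_pic``.
    """
    df = site_table.df
    sub = df[df["gene_id"] == gene_id].drop_duplicates("pirna")
    if sub.empty:
        raise KeyError(f"gene {gene_id} absent from site table")
    totals: dict[str, float] = {}
    unmapped = 0.0
    for seq, count in zip(sub["pirna"], sub["count"].astype(float)):
        sources = source_weights.get(seq)
        if not sources:
            unmapped += count
            if include_unmapped:
                totals[UNMAPPED] = totals.get(UNMAPPED, 0.0) + count
            continue
        for label, share in sources.items():
            totals[label] = totals.get(label, 0.0) + count * share
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError(f"gene {gene_id}: no mapped targeting weight")
    entries = sorted(
        ((label, w / grand) for label, w in totals.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    cluster_entries = [
        (label, f) for label, f in entries if label not in (NON_PIC, UNMAPPED)
    ]
    major = [(label, f) for label, f in cluster_entries if f >= minor_threshold]
    summary = {
        "top": major[0][1] if len(major) > 0 else 0.0,
        "second": major[1][1] if len(major) > 1 else 0.0,
        "third": major[2][1] if len(major) > 2 else 0.0,
        "minor_lt5": sum(f for _, f in cluster_entries if f < minor_threshold)
        + sum(f for _, f in major[3:]),
        "non_pic": dict(entries).get(NON_PIC, 0.0),
    }
    if include_unmapped:
        summary["unmapped"] = dict(entries).get(UNMAPPED, 0.0)
    return ClusterDecomposition(
        gene_id=gene_id, entries=entries, summary=summary, unmapped_weight=unmapped
    )


def pic_fraction(
    site_table: SiteTable, source_weights: dict[str, dict[str, float]]
) -> float:
    """Fraction of all targeting weight that originates inside clusters."""
    df = site_table.df.drop_duplicates("pirna")
    pic = 0.0
    total = 0.0
    for seq, count in zip(df["pirna"], df["count"].astype(float)):
        sources = source_weights.get(seq)
        if not sources:
            continue
        total += count
        pic += count * sum(s for label, s in sources.items() if label != NON_PIC)
    if total == 0:
        raise ValueError("no mapped targeting weight")
    return pic / total


# ---------------------------------------------------------------------------
# cis / trans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CisTransLabel:
    pirna: str
    gene_id: str
    label: str  # cis | trans


def classify_cis_trans(
    site_table: SiteTable,
    hits: list[GenomicHit],
    gene_models: dict[str, GeneModel],
) -> pd.DataFrame:
    """Label each (piRNA, targeted gene) pair cis or trans.

    cis means some perfect genomic hit of the piRNA overlaps the target
    gene's exon-union locus (any interval overlap, either strand) — the
    piRNA could derive from an antisense transcript of the locus itself.
    Everything else is trans.  Returns a DataFrame ``pirna, gene_id,
    label`` plus a ``trans_fraction`` in ``df.attrs`` (weighted by read
    counts).
    """
    hits_by_seq: dict[str, list[GenomicHit]] = {}
    for h in hits:
        hits_by_seq.setdefault(h.pirna, []).append(h)

    df = site_table.df.drop_duplicates(["pirna", "gene_id"])
    rows = []
    trans_w = 0.0
    total_w = 0.0
    for seq, gid, count in zip(df["pirna"], df["gene_id"], df["count"].astype(float)):
        gene = gene_models[gid]
        label = "trans"
        for h in hits_by_seq.get(seq, ()):
            if h.chrom != gene.chrom:
                continue
            if any(h.start < e and h.end > s for s, e in gene.exons):
                label = "cis"
                break
        rows.append({"pirna": seq, "gene_id": gid, "label": label})
        total_w += count
        if label == "trans":
            trans_w += count
    out = pd.DataFrame(rows, columns=["pirna", "gene_id", "label"])
    out.attrs["trans_fraction"] = trans_w / total_w if total_w else float("nan")
    return out
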