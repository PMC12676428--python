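"""Genomic I/O and core containers.

This module owns the data model shared by the whole pipeline:

* :class:`Genome` — named chromosome sequences (uppercase DNA).
* :class:`GeneModel` — a gene as the genomic union of its annotated exons
  plus an optional CDS span.  One model per gene: isoforms are collapsed
  so that piRNA density can be drawn on a single exon track.
* :class:`TranscriptSeq` — the spliced mRNA (5'->3' in mRNA sense) with a
  per-base feature map (5UTR/CDS/3UTR), exon ordinals and a projection
  back to genomic coordinates.
* :class:`PiRNAPool` — unique small-RNA sequences with read counts, the
  unit of all downstream weighting.

Coordinates are 0-based half-open everywhere internally; GTF's 1-based
closed convention is converted at the parsing boundary.  piRNA nucleotide
positions, in contrast, are 1-based from the 5' end throughout the
package (so that "nt 2-21" reads the way small-RNA biologists write it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: per-base feature labels used in TranscriptSeq.feature_map
UTR5, CDS, UTR3 = "5UTR", "CDS", "3UTR"
#: label for transcripts of genes without CDS annotation (kept for
#: matching, excluded from metagene profiles)
CDS_ABSENT = "CDS-absent"

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 40


class ParseError(ValueError):
    """Malformed input record; message names the offending line."""


class CoordinateError(ValueError):
    """A feature falls outside its chromosome."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-pairs)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

class Genome:
    """Named chromosome sequences, uppercase DNA over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, s in sequences.items():
            s = s.upper()
            if not s:
                raise ValueError(f"empty sequence for {name!r}")
            self.sequences[name] = s

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if start < 0 or end > len(self.sequences[chrom]) or start >= end:
            raise CoordinateError(
                f"interval [{start},{end}) outside {chrom} "
                f"(length {len(self.sequences[chrom])})"
            )
        s = self.sequences[chrom][start:end]
        return revcomp(s) if strand == "-" else s

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ParseError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        recs = [
            SeqRecord(Seq(s), id=name, description="")
            for name, s in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(recs)


# ---------------------------------------------------------------------------
# Gene models and transcripts
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene as collapsed exon union (0-based half-open intervals)."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if self.cds_span is not None:
            lo, hi = self.cds_span
            if not (self.exons[0][0] <= lo < hi <= self.exons[-1][1]):
                raise ValueError(
                    f"CDS span {self.cds_span} outside exon union of {self.gene_id}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


def merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge possibly overlapping half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if s >= e:
            raise ValueError(f"empty interval ({s},{e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class TranscriptSeq:
    """Spliced mRNA with feature map and genomic provenance.

    ``sequence[i]`` reads 5'->3' in mRNA sense.  ``genomic_positions[i]``
    is the genomic coordinate of that base on ``chrom`` (strand taken
    from the gene model); for minus-strand genes the array is descending.
    """

    gene_id: str
    chrom: str
    strand: str
    sequence: str
    feature_map: np.ndarray          # dtype object/str labels per base
    exon_index: np.ndarray           # 1-based exon ordinal in mRNA order
    genomic_positions: np.ndarray    # genomic coordinate per base

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (len(self.feature_map) == len(self.exon_index) == len(self.genomic_positions) == n):
            raise ValueError("parallel arrays must match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_cds(self) -> bool:
        return CDS in self.feature_map

    def feature_lengths(self) -> dict[str, int]:
        labels, counts = np.unique(self.feature_map, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def build_transcript(gene: GeneModel, genome: Genome) -> TranscriptSeq:
    """Splice a gene's exon union into its mRNA-sense transcript.

    Exon substrings are concatenated in genomic order and the whole
    product reverse-complemented for minus-strand genes, so the result
    always reads 5'->3' in mRNA sense.  Feature labels come from
    projecting the CDS genomic span; a gene without CDS annotation is
    labelled ``CDS-absent`` throughout (kept for matching, excluded from
    metagene profiles).
    """
    chrom_len = genome.length(gene.chrom)
    for s, e in gene.exons:
        if s < 0 or e > chrom_len:
            raise CoordinateError(
                f"exon ({s},{e}) of {gene.gene_id} outside {gene.chrom}"
            )
    parts = [genome[gene.chrom][s:e] for s, e in gene.exons]
    seq = "".join(parts)
    gpos = np.concatenate([np.arange(s, e) for s, e in gene.exons])
    exon_ord = np.concatenate(
        [np.full(e - s, i + 1) for i, (s, e) in enumerate(gene.exons)]
    )
    if gene.strand == "-":
        seq = revcomp(seq)
        gpos = gpos[::-1].copy()
        n_ex = len(gene.exons)
        exon_ord = (n_ex + 1 - exon_ord)[::-1].copy()

    n = len(seq)
    if gene.cds_span is None:
        fmap = np.full(n, CDS_ABSENT, dtype=object)
    else:
        lo, hi = gene.cds_span
        in_cds = (gpos >= lo) & (gpos < hi)
        fmap = np.empty(n, dtype=object)
        idx = np.flatnonzero(in_cds)
        if idx.size == 0:
            raise ValueError(f"CDS span of {gene.gene_id} covers no exonic base")
        fmap[: idx[0]] = UTR5
        fmap[idx[0]: idx[-1] + 1] = CDS
        fmap[idx[-1] + 1:] = UTR3
    return TranscriptSeq(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        sequence=seq,
        feature_map=fmap,
        exon_index=exon_ord.astype(np.int64),
        genomic_positions=gpos.astype(np.int64),
    )


def build_transcriptome(
    genes: Iterable[GeneModel], genome: Genome
) -> dict[str, TranscriptSeq]:
    return {g.gene_id: build_transcript(g, genome) for g in genes}


# ---------------------------------------------------------------------------
# Cluster annotations (BED6)
# ---------------------------------------------------------------------------

@dataclass
class ClusterAnnotation:
    """One piRNA cluster locus; strand_mode records the precursor strand."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    strand_mode: str = "plus"  # plus | minus | bidirectional

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty cluster interval for {self.cluster_id}")
        if self.strand_mode not in ("plus", "minus", "bidirectional"):
            raise ValueError(f"bad strand_mode {self.strand_mode!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


_BED_STRAND = {"plus": "+", "minus": "-", "bidirectional": "."}
_STRAND_MODE = {"+": "plus", "-": "minus", ".": "bidirectional"}


def read_bed6(path: str | Path) -> list[ClusterAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED fields")
            try:
                chrom, start, end, name, _score, strand = fields[:6]
                out.append(
                    ClusterAnnotation(
                        cluster_id=name,
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand_mode=_STRAND_MODE[strand],
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed6(clusters: Sequence[ClusterAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t0\t"
                f"{_BED_STRAND[c.strand_mode]}\n"
            )


# ---------------------------------------------------------------------------
# GTF gene models (via gffutils)
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse GTF exon/CDS features into collapsed per-gene models.

    Exons of all transcripts of a gene are merged into their genomic
    union; CDS labels come from the union span of all CDS records.
    GTF's 1-based closed coordinates become 0-based half-open here.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted exception types
        raise ParseError(f"cannot parse GTF {path}: {exc}") from exc

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    tx: dict[str, set[str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ParseError(f"{path}: feature without gene_id at {feat.start}")
        meta.setdefault(gid, (feat.seqid, feat.strand))
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> half-open
        if feat.featuretype == "exon":
            exons.setdefault(gid, []).append(iv)
        else:
            cds.setdefault(gid, []).append(iv)
        for tid in feat.attributes.get("transcript_id", []):
            tx.setdefault(gid, set()).add(tid)

    models = []
    for gid, ivals in exons.items():
        chrom, strand = meta[gid]
        span = None
        if gid in cds:
            cs = sorted(cds[gid])
            span = (cs[0][0], max(e for _, e in cs))
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=ivals,
                cds_span=span,
                transcript_ids=sorted(tx.get(gid, ())),
            )
        )
    models.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return models


def write_gtf(genes: Sequence[GeneModel], path: str | Path, source: str = "piswarm") -> None:
    with open(path, "w") as fh:
        for g in genes:
            tid = g.transcript_ids[0] if g.transcript_ids else f"{g.gene_id}.t1"
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            if g.cds_span is not None:
                lo, hi = g.cds_span
                for s, e in g.exons:
                    cs, ce = max(s, lo), min(e, hi)
                    if cs < ce:
                        fh.write(
                            f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{g.strand}\t0\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# piRNA pools
# ---------------------------------------------------------------------------

@dataclass
class PiRNAPool:
    """Unique small-RNA sequences with read counts."""

    records: list[tuple[str, int]]
    total_reads: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.total_reads != sum(c for _, c in self.records):
            raise ValueError("total_reads must equal the sum of counts")

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> dict[str, int]:
        return dict(self.records)

    def subset(self, sequences: Iterable[str]) -> "PiRNAPool":
        keep = set(sequences)
        recs = [(s, c) for s, c in self.records if s in keep]
        return PiRNAPool(recs, sum(c for _, c in recs))


def collapse_reads(
    reads: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> PiRNAPool:
    """Merge identical reads into a weighted pool.

    Reads containing N or outside [min_len, max_len] are dropped and
    tallied in ``n_excluded``.  U is normalised to T so FASTA dumps of
    RNA reads collapse with their DNA spellings.
    """
    counts: dict[str, int] = {}
    kept = 0
    excluded = 0
    for r in reads:
        r = r.upper().replace("U", "T")
        if "N" in r or not (min_len <= len(r) <= max_len):
            excluded += 1
            continue
        counts[r] = counts.get(r, 0) + 1
        kept += 1
    if excluded:
        logger.info("collapse_reads: excluded %d reads (N or length)", excluded)
    records = sorted(counts.items())
    return PiRNAPool(records=records, total_reads=kept, n_excluded=excluded)


def iter_reads(path: str | Path, fmt: str | None = None) -> Iterator[str]:
    """Yield raw read sequences from FASTA/FASTQ (qualities ignored).

    Collapsed-FASTA headers of the form ``>id count=N`` expand back to N
    occurrences so that re-collapsing is lossless.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        n = 1
        for tok in rec.description.split():
            if tok.startswith("count="):
                n = int(tok[len("count="):])
        for _ in range(n):
            yield str(rec.seq)


def read_pool(path: str | Path, **kwargs) -> PiRNAPool:
    return collapse_reads(iter_reads(path), **kwargs)


def write_pool(pool: PiRNAPool, path: str | Path) -> None:
    """Write a collapsed pool as FASTA with ``count=N`` headers."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(pool.records, 1):
            fh.write(f">pi{i} count={count}\n{seq}\n")


def write_reads_fasta(reads: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f">read{i}\n{r}\n")


# ---------------------------------------------------------------------------
# Generic tables
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse TSV {path}: {exc}") from exc


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
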