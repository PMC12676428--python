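"""Synthetic genomes, clusters, pseudogene insertions and piRNA pools.

The generator emulates the data model the pipeline is built for:

* a random genome carrying multi-exon genes and discrete piRNA
  clusters that emit single-stranded precursors;
* processed or partly processed pseudogene insertions inside clusters —
  spliced (optionally intron-retaining) copies of a source transcript,
  5'-truncated, point-diverged, inserted antisense and flanked by exact
  target-site duplications, the anatomy of a LINE-mediated
  retrotransposition event;
* piRNA pools sampled from precursor strands (lengths ~26-32 nt,
  tunable 1U start-site bias, random genomic background, optional
  ping-pong mate pairs with 10-nt 5' overlaps);
* gene-level log2 fold-change tables with planted upregulation of the
  top targets.

Every sampled read is an exact substring of the emitted genome
(strand-aware): the 1U bias is achieved by biased start-site selection,
never by editing bases, so perfect genomic mapping stays lossless.

Point divergence uses quasi-regular mutation spacing (even spacing with
small jitter, capped so no gap exceeds ``MAX_MUTATION_GAP``).  At the
divergence rates used here (>= ~4%) this guarantees that every
piRNA-length window of the insertion carries at least one diverged
position, so fragment-derived piRNAs map uniquely back to their source
locus — the property that makes cluster attribution on synthetic data
exact and mirrors the aged, well-diverged pseudogene fragments found in
real clusters.

A handful of named configurations ship with the package (YAML files):
``minimal``, ``fig1a`` (rank-abundance panel: an 88-gene top set
holding 70% of targeting weight, the top gene 12%), ``spin1like`` (one
dominant cluster at 81% emission for a single target, 5% divergence,
14-nt TSD, exons 3-5, 5'-truncated), ``ago2like`` (partly processed,
one retained intron), ``pingpong`` / ``pingpong_null`` (mate pairs
planted at 30% of reads, and the matched primary-only control).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .io import (
    ClusterAnnotation,
    GeneModel,
    Genome,
    TranscriptSeq,
    build_transcript,
    revcomp,
    write_bed6,
    write_gtf,
    write_reads_fasta,
    write_tsv,
)

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
#: mutation spacing cap that keeps every piRNA-length window diverged
MAX_MUTATION_GAP = 24


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    gc_content: float = 0.42
    length: int | None = None
    intergenic_gap: tuple[int, int] = (200, 800)
    chrom: str = "chr1"


@dataclass
class GeneConfig:
    gene_id: str
    n_exons: int = 1
    exon_length: tuple[int, int] = (180, 320)
    intron_length: tuple[int, int] = (150, 400)
    utr5_length: int = 100
    utr3_length: int = 300
    strand: str = "+"
    no_cds: bool = False


@dataclass
class ClusterConfig:
    cluster_id: str
    strand_mode: str = "plus"
    padding: int = 200
    spacer: int = 100
    extra_length: int = 0


@dataclass
class PGFConfig:
    pgf_id: str
    source_gene: str
    host_cluster: str
    exon_range: tuple[int, int] = (1, 1)
    five_prime_truncation: int = 0
    divergence: float = 0.0
    tsd_length: int = 14
    orientation: str = "antisense"   # antisense | sense (to the precursor)
    include_intron: bool = False
    intron_after: int | None = None  # exon ordinal; default: next-to-last of range


@dataclass
class TargetPanelConfig:
    """Bulk rank-abundance panel: many single-exon genes, each with a
    perfect antisense copy in a host cluster, emission weights following
    a Zipf head plus a uniform tail."""

    host_cluster: str
    n_head: int = 88
    head_coverage: float = 0.70
    top1_fraction: float = 0.12
    n_tail: int = 250
    utr5_length: int = 60
    cds_length: int = 220
    utr3_length: int = 140
    tsd_length: int = 10


@dataclass
class SamplingConfig:
    total_reads: int = 20000
    length_range: tuple[int, int] = (26, 32)
    u1_probability: float = 0.8
    background_fraction: float = 0.05
    pingpong_fraction: float = 0.0
    error_rate: float = 0.0
    emission: dict[str, float] = field(default_factory=dict)


@dataclass
class ExpressionConfig:
    effect_size_top: float = 1.0
    effect_size_lower: float = 0.1
    sd: float = 0.5
    n_non_targets: int = 200
    coverage: float = 0.70


@dataclass
class SimConfig:
    name: str = "custom"
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    genes: list[GeneConfig] = field(default_factory=list)
    clusters: list[ClusterConfig] = field(default_factory=list)
    pgfs: list[PGFConfig] = field(default_factory=list)
    target_panel: TargetPanelConfig | None = None
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def replace_sampling(self, **kwargs) -> "SimConfig":
        return replace(self, sampling=replace(self.sampling, **kwargs))


def _pair(v) -> tuple[int, int]:
    a, b = v
    return int(a), int(b)


def config_from_dict(d: dict) -> SimConfig:
    g = d.get("genome", {})
    genome = GenomeConfig(
        gc_content=float(g.get("gc_content", 0.42)),
        length=g.get("length"),
        intergenic_gap=_pair(g.get("intergenic_gap", (200, 800))),
        chrom=g.get("chrom", "chr1"),
    )
    genes = [
        GeneConfig(
            gene_id=x["gene_id"],
            n_exons=int(x.get("n_exons", 1)),
            exon_length=_pair(x.get("exon_length", (180, 320))),
            intron_length=_pair(x.get("intron_length", (150, 400))),
            utr5_length=int(x.get("utr5_length", 100)),
            utr3_length=int(x.get("utr3_length", 300)),
            strand=x.get("strand", "+"),
            no_cds=bool(x.get("no_cds", False)),
        )
        for x in d.get("genes", [])
    ]
    clusters = [
        ClusterConfig(
            cluster_id=x["cluster_id"],
            strand_mode=x.get("strand_mode", "plus"),
            padding=int(x.get("padding", 200)),
            spacer=int(x.get("spacer", 100)),
            extra_length=int(x.get("extra_length", 0)),
        )
        for x in d.get("clusters", [])
    ]
    pgfs = [
        PGFConfig(
            pgf_id=x["pgf_id"],
            source_gene=x["source_gene"],
            host_cluster=x["host_cluster"],
            exon_range=_pair(x.get("exon_range", (1, 1))),
            five_prime_truncation=int(x.get("five_prime_truncation", 0)),
            divergence=float(x.get("divergence", 0.0)),
            tsd_length=int(x.get("tsd_length", 14)),
            orientation=x.get("orientation", "antisense"),
            include_intron=bool(x.get("include_intron", False)),
            intron_after=x.get("intron_after"),
        )
        for x in d.get("pgfs", [])
    ]
    panel = None
    if "target_panel" in d:
        x = d["target_panel"]
        panel = TargetPanelConfig(
            host_cluster=x["host_cluster"],
            n_head=int(x.get("n_head", 88)),
            head_coverage=float(x.get("head_coverage", 0.70)),
            top1_fraction=float(x.get("top1_fraction", 0.12)),
            n_tail=int(x.get("n_tail", 250)),
            utr5_length=int(x.get("utr5_length", 60)),
            cds_length=int(x.get("cds_length", 220)),
            utr3_length=int(x.get("utr3_length", 140)),
            tsd_length=int(x.get("tsd_length", 10)),
        )
    s = d.get("pirna_sampling", {})
    sampling = SamplingConfig(
        total_reads=int(s.get("total_reads", 20000)),
        length_range=_pair(s.get("length_range", (26, 32))),
        u1_probability=float(s.get("u1_probability", 0.8)),
        background_fraction=float(s.get("background_fraction", 0.05)),
        pingpong_fraction=float(s.get("pingpong_fraction", 0.0)),
        error_rate=float(s.get("error_rate", 0.0)),
        emission={str(k): float(v) for k, v in s.get("emission", {}).items()},
    )
    e = d.get("expression", {})
    expression = ExpressionConfig(
        effect_size_top=float(e.get("effect_size_top", 1.0)),
        effect_size_lower=float(e.get("effect_size_lower", 0.1)),
        sd=float(e.get("sd", 0.5)),
        n_non_targets=int(e.get("n_non_targets", 200)),
        coverage=float(e.get("coverage", 0.70)),
    )
    return SimConfig(
        name=d.get("name", "custom"),
        seed=int(d.get("seed", 0)),
        genome=genome,
        genes=genes,
        clusters=clusters,
        pgfs=pgfs,
        target_panel=panel,
        sampling=sampling,
        expression=expression,
    )


def load_config(name_or_path: str | Path) -> SimConfig:
    """Load a shipped named config ("spin1like", ...) or a YAML path."""
    path = Path(name_or_path)
    if not path.exists():
        res = importlib.resources.files("piswarm") / "configs" / f"{name_or_path}.yaml"
        if not res.is_file():
            raise FileNotFoundError(f"no config file or named config {name_or_path!r}")
        return config_from_dict(yaml.safe_load(res.read_text()))
    return config_from_dict(yaml.safe_load(path.read_text()))


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def mutate_spaced(
    seq: str, rate: float, rng: np.random.Generator, max_gap: int = MAX_MUTATION_GAP
) -> tuple[str, int]:
    """Substitute ~rate of positions at quasi-regular spacing.

    Mutations are placed at even intervals with a small random jitter,
    capped so consecutive mutations (and the distances to either end)
    never exceed ``max_gap`` when the rate allows it.  Returns the
    mutated sequence and the number of substitutions.
    """
    if rate < 0 or rate >= 0.5:
        raise ValueError("divergence rate must be in [0, 0.5)")
    L = len(seq)
    m = int(round(rate * L))
    if m == 0:
        return seq, 0
    spacing = L / m
    jitter_cap = max(0, int(min(max_gap - spacing, spacing - 1) // 2))
    positions = []
    for j in range(m):
        base_pos = int((j + 0.5) * spacing)
        pos = base_pos + int(rng.integers(-jitter_cap, jitter_cap + 1))
        positions.append(min(max(pos, 0), L - 1))
    positions = sorted(set(positions))
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return "".join(out), len(positions)


# ---------------------------------------------------------------------------
# Gene loci
# ---------------------------------------------------------------------------

@dataclass
class _GeneLocus:
    config: GeneConfig
    seq: str                       # locus sequence (genome plus strand)
    exons_local: list[tuple[int, int]]
    cds_local: tuple[int, int] | None
    transcript_local: TranscriptSeq
    model_local: GeneModel


def _build_gene_locus(cfg: GeneConfig, gc: float, rng: np.random.Generator) -> _GeneLocus:
    exon_lens = [
        int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        for _ in range(cfg.n_exons)
    ]
    intron_lens = [
        int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        for _ in range(max(0, cfg.n_exons - 1))
    ]
    pos = 0
    exons = []
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    seq = random_dna(rng, pos, gc)
    tx_len = sum(exon_lens)
    cds_local = None
    if not cfg.no_cds:
        if cfg.utr5_length + cfg.utr3_length >= tx_len:
            raise ValueError(f"UTRs of {cfg.gene_id} exceed transcript length")
        model0 = GeneModel(cfg.gene_id, "_local", cfg.strand, list(exons))
        tr0 = build_transcript(model0, Genome({"_local": seq}))
        cds_positions = tr0.genomic_positions[
            cfg.utr5_length: tx_len - cfg.utr3_length
        ]
        cds_local = (int(cds_positions.min()), int(cds_positions.max()) + 1)
    model = GeneModel(cfg.gene_id, "_local", cfg.strand, list(exons), cds_local)
    tr = build_transcript(model, Genome({"_local": seq}))
    return _GeneLocus(cfg, seq, exons, cds_local, tr, model)


# ---------------------------------------------------------------------------
# Pseudogene inserts
# ---------------------------------------------------------------------------

@dataclass
class PGFInsert:
    config: PGFConfig
    seq: str              # as written on the cluster/genome plus strand
    n_mutations: int
    source_interval: tuple[int, int]   # transcript coords covered (pre-divergence)
    retained_intron: int | None


def build_pgf_insert(
    locus: _GeneLocus,
    cfg: PGFConfig,
    rng: np.random.Generator,
    host_strand_mode: str = "plus",
) -> PGFInsert:
    """Construct the insertion sequence of one pseudogene fragment.

    splice -> optional intron retention -> 5' truncation -> point
    divergence -> orientation.  The sequence is returned as it will
    appear on the genome plus strand.  Orientation is defined relative
    to the host cluster's precursor strand: an antisense fragment must
    read as the reverse complement of the mRNA segment *on the emitting
    strand*, so for a minus-strand cluster the plus strand carries the
    segment itself.
    """
    tr = locus.transcript_local
    e1, e2 = cfg.exon_range
    mask = (tr.exon_index >= e1) & (tr.exon_index <= e2)
    if not mask.any():
        raise ValueError(f"exon range {cfg.exon_range} empty for {cfg.source_gene}")
    idx = np.flatnonzero(mask)
    lo, hi = int(idx[0]), int(idx[-1]) + 1

    retained = None
    if cfg.include_intron:
        retained = cfg.intron_after if cfg.intron_after is not None else max(e1, e2 - 1)
        if not (e1 <= retained < e2):
            raise ValueError("intron_after must lie within the exon range")
        # mRNA-order intron `retained` sits between exons retained/retained+1
        introns = locus.model_local.introns()
        if locus.config.strand == "-":
            introns = introns[::-1]
        gi_s, gi_e = introns[retained - 1]
        intron_seq = Genome({"_local": locus.seq}).fetch(
            "_local", gi_s, gi_e, locus.config.strand
        )
        break_at = int(np.flatnonzero(tr.exon_index == retained)[-1]) + 1
        segment = tr.sequence[lo:break_at] + intron_seq + tr.sequence[break_at:hi]
    else:
        segment = tr.sequence[lo:hi]

    if cfg.five_prime_truncation >= len(segment):
        raise ValueError("truncation removes the whole fragment")
    segment = segment[cfg.five_prime_truncation:]
    mutated, n_mut = mutate_spaced(segment, cfg.divergence, rng)
    if cfg.orientation not in ("antisense", "sense"):
        raise ValueError(f"bad orientation {cfg.orientation!r}")
    antisense_on_emitting_strand = cfg.orientation == "antisense"
    # bidirectional clusters emit from both strands; use plus as reference
    emitting_minus = host_strand_mode == "minus"
    if antisense_on_emitting_strand != emitting_minus:
        plus_seq = revcomp(mutated)
    else:
        plus_seq = mutated
    return PGFInsert(
        config=cfg,
        seq=plus_seq,
        n_mutations=n_mut,
        source_interval=(lo + cfg.five_prime_truncation, hi),
        retained_intron=retained,
    )


# ---------------------------------------------------------------------------
# Panel expansion (fig1a-style rank-abundance fixtures)
# ---------------------------------------------------------------------------

def zipf_head_weights(n_head: int, head_coverage: float, top1_fraction: float) -> np.ndarray:
    """Zipf exponent solved so the head holds ``head_coverage`` of the
    weight and rank 1 holds ``top1_fraction`` of the total."""
    target = head_coverage / top1_fraction

    def gap(s: float) -> float:
        return np.sum(np.arange(1, n_head + 1, dtype=float) ** (-s)) - target

    s = optimize.brentq(gap, 0.01, 3.0)
    w = np.arange(1, n_head + 1, dtype=float) ** (-s)
    return head_coverage * w / w.sum()


def _expand_panel(config: SimConfig) -> SimConfig:
    panel = config.target_panel
    if panel is None:
        return config
    head_w = zipf_head_weights(panel.n_head, panel.head_coverage, panel.top1_fraction)
    tail_w = np.full(panel.n_tail, (1.0 - panel.head_coverage) / panel.n_tail)
    weights = np.concatenate([head_w, tail_w])
    genes = list(config.genes)
    pgfs = list(config.pgfs)
    emission = dict(config.sampling.emission)
    tx_len = panel.utr5_length + panel.cds_length + panel.utr3_length
    for i, w in enumerate(weights, 1):
        gid = f"T{i:04d}"
        genes.append(
            GeneConfig(
                gene_id=gid,
                n_exons=1,
                exon_length=(tx_len, tx_len),
                utr5_length=panel.utr5_length,
                utr3_length=panel.utr3_length,
            )
        )
        pid = f"panel_{gid}"
        pgfs.append(
            PGFConfig(
                pgf_id=pid,
                source_gene=gid,
                host_cluster=panel.host_cluster,
                exon_range=(1, 1),
                divergence=0.0,
                tsd_length=panel.tsd_length,
                orientation="antisense",
            )
        )
        emission[f"pgf:{pid}"] = float(w)
    return replace(
        config,
        genes=genes,
        pgfs=pgfs,
        target_panel=None,
        sampling=replace(config.sampling, emission=emission),
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genome: Genome
    genes: list[GeneModel]
    clusters: list[ClusterAnnotation]
    pgf_truth: pd.DataFrame
    reads: list[str]
    read_truth: pd.DataFrame
    expression: pd.DataFrame
    target_weights: dict[str, float]

    def gene_models(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def pgf_interval(self, pgf_id: str) -> tuple[str, int, int]:
        row = self.pgf_truth.set_index("pgf_id").loc[pgf_id]
        return str(row["chrom"]), int(row["start"]), int(row["end"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        write_gtf(self.genes, outdir / "genes.gtf")
        write_bed6(self.clusters, outdir / "clusters.bed")
        write_reads_fasta(self.reads, outdir / "reads.fa")
        write_tsv(self.pgf_truth, outdir / "pgf_truth.tsv")
        write_tsv(self.read_truth, outdir / "read_truth.tsv")
        write_tsv(self.expression, outdir / "expression.tsv")


def simulate_genome_and_annotation(
    config: SimConfig, rng: np.random.Generator
) -> tuple[Genome, list[GeneModel], list[ClusterAnnotation], pd.DataFrame, dict]:
    """Assemble the genome with genes, clusters and planted insertions.

    Returns the genome, gene models, cluster annotations, the PGF truth
    table and a dict of source intervals used by the read sampler.
    """
    gc = config.genome.gc_content
    loci = {g.gene_id: _build_gene_locus(g, gc, rng) for g in config.genes}
    inserts: dict[str, PGFInsert] = {}
    cluster_modes = {c.cluster_id: c.strand_mode for c in config.clusters}
    for p in config.pgfs:
        if p.source_gene not in loci:
            raise ValueError(f"PGF {p.pgf_id} references unknown gene {p.source_gene}")
        if p.host_cluster not in cluster_modes:
            raise ValueError(f"PGF {p.pgf_id} references unknown cluster {p.host_cluster}")
        inserts[p.pgf_id] = build_pgf_insert(
            loci[p.source_gene], p, rng, cluster_modes[p.host_cluster]
        )

    # cluster sequences with planted insertions
    cluster_parts: dict[str, tuple[str, list[tuple[str, int, int]]]] = {}
    for c in config.clusters:
        hosted = [p for p in config.pgfs if p.host_cluster == c.cluster_id]
        parts = [random_dna(rng, c.padding, gc)]
        pos = c.padding
        insert_spans = []
        for p in hosted:
            ins = inserts[p.pgf_id]
            tsd = random_dna(rng, p.tsd_length, gc)
            # guard against single-base TSD extension past the planted length
            left = parts[-1]
            if left and left[-1] == ins.seq[-1]:
                parts[-1] = left[:-1] + _other_base(left[-1], rng)
            parts.append(tsd)
            pos += p.tsd_length
            insert_spans.append((p.pgf_id, pos, pos + len(ins.seq)))
            parts.append(ins.seq)
            pos += len(ins.seq)
            parts.append(tsd)
            pos += p.tsd_length
            spacer = random_dna(rng, c.spacer, gc)
            if spacer and spacer[0] == ins.seq[0]:
                spacer = _other_base(spacer[0], rng) + spacer[1:]
            parts.append(spacer)
            pos += c.spacer
        tail = random_dna(rng, c.extra_length + c.padding, gc)
        parts.append(tail)
        pos += len(tail)
        cluster_parts[c.cluster_id] = ("".join(parts), insert_spans)

    # lay features along the chromosome with random intergenic gaps
    lo_gap, hi_gap = config.genome.intergenic_gap
    chrom = config.genome.chrom
    segments: list[str] = []
    cursor = 0

    def add_gap() -> None:
        nonlocal cursor
        gap = int(rng.integers(lo_gap, hi_gap + 1))
        segments.append(random_dna(rng, gap, gc))
        cursor += gap

    gene_models: list[GeneModel] = []
    add_gap()
    for g in config.genes:
        locus = loci[g.gene_id]
        offset = cursor
        segments.append(locus.seq)
        cursor += len(locus.seq)
        exons = [(s + offset, e + offset) for s, e in locus.exons_local]
        cds = (
            (locus.cds_local[0] + offset, locus.cds_local[1] + offset)
            if locus.cds_local
            else None
        )
        gene_models.append(
            GeneModel(g.gene_id, chrom, g.strand, exons, cds, [f"{g.gene_id}.t1"])
        )
        add_gap()

    clusters: list[ClusterAnnotation] = []
    pgf_rows = []
    sources: dict[str, dict] = {}
    for c in config.clusters:
        cseq, spans = cluster_parts[c.cluster_id]
        offset = cursor
        segments.append(cseq)
        cursor += len(cseq)
        ann = ClusterAnnotation(c.cluster_id, chrom, offset, offset + len(cseq), c.strand_mode)
        clusters.append(ann)
        sources[f"cluster:{c.cluster_id}"] = {
            "chrom": chrom,
            "start": offset,
            "end": offset + len(cseq),
            "strand_mode": c.strand_mode,
            "cluster_id": c.cluster_id,
            "target_gene": "",
            "in_pgf": False,
        }
        for pgf_id, s, e in spans:
            p = next(x for x in config.pgfs if x.pgf_id == pgf_id)
            ins = inserts[pgf_id]
            pgf_rows.append(
                {
                    "pgf_id": pgf_id,
                    "cluster_id": c.cluster_id,
                    "chrom": chrom,
                    "start": s + offset,
                    "end": e + offset,
                    "source_gene": p.source_gene,
                    "exon_start": p.exon_range[0],
                    "exon_end": p.exon_range[1],
                    "five_prime_truncation": p.five_prime_truncation,
                    "divergence": p.divergence,
                    "n_mutations": ins.n_mutations,
                    "insert_length": len(ins.seq),
                    "tsd_length": p.tsd_length,
                    "orientation": p.orientation,
                    "include_intron": p.include_intron,
                    "retained_intron": ins.retained_intron or 0,
                }
            )
            sources[f"pgf:{pgf_id}"] = {
                "chrom": chrom,
                "start": s + offset,
                "end": e + offset,
                "strand_mode": c.strand_mode,
                "cluster_id": c.cluster_id,
                "target_gene": p.source_gene if p.orientation == "antisense" else "",
                "in_pgf": True,
            }
        add_gap()

    assembled = "".join(segments)
    if config.genome.length is not None:
        if len(assembled) > config.genome.length:
            raise ValueError(
                f"requested features need {len(assembled)} nt but genome.length "
                f"is {config.genome.length}; increase the genome length"
            )
        assembled += random_dna(rng, config.genome.length - len(assembled), gc)
    genome = Genome({chrom: assembled})
    pgf_truth = pd.DataFrame(pgf_rows)
    return genome, gene_models, clusters, pgf_truth, sources


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def _strand_base_positions(genome: Genome, src: dict, strand: str) -> dict[str, np.ndarray]:
    """5'-start candidates inside a source split by whether the read
    would start with T on the emitting strand."""
    seq = np.frombuffer(
        genome[src["chrom"]][src["start"]: src["end"]].encode(), dtype="S1"
    )
    pos = np.arange(src["start"], src["end"])
    if strand == "+":
        is_t = seq == b"T"
    else:
        is_t = seq == b"A"  # minus-strand base is the complement
    return {"T": pos[is_t], "other": pos[~is_t]}


def sample_pirnas(
    genome: Genome,
    sources: dict[str, dict],
    sampling: SamplingConfig,
    rng: np.random.Generator,
) -> tuple[list[str], pd.DataFrame]:
    """Sample a piRNA read pool with per-read truth records.

    Reads are genome substrings: a 5' start is drawn inside the chosen
    source (with probability ``u1_probability`` from the positions that
    begin with U on the emitting strand), the length uniformly from
    ``length_range``.  Background reads come from random genomic
    positions on random strands; ping-pong mates sit on the strand
    opposite a sampled primary read with a 10-nt 5' overlap.
    """
    lmin, lmax = sampling.length_range
    total = sampling.total_reads
    n_bg = int(round(total * sampling.background_fraction))
    n_pp = int(round(total * sampling.pingpong_fraction))
    emission = dict(sampling.emission)
    if not emission:
        emission = {k: 1.0 for k in sources if k.startswith("cluster:")}
    missing = [k for k in emission if k not in sources]
    if missing:
        raise ValueError(f"emission references unknown sources: {missing}")
    labels = sorted(emission)
    probs = np.array([emission[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    n_src = total - n_bg - n_pp
    if n_src < 0:
        raise ValueError("background + pingpong fractions exceed 1")
    counts = rng.multinomial(n_src, probs)

    chrom_names = sorted(genome.sequences)
    pos_cache: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    def draw_start(label: str, strand: str) -> int:
        key = (label, strand)
        if key not in pos_cache:
            pos_cache[key] = _strand_base_positions(genome, sources[label], strand)
        cand = pos_cache[key]
        want_t = rng.random() < sampling.u1_probability
        pool = cand["T"] if want_t else cand["other"]
        if pool.size == 0:
            logger.warning("source %s has no %s-start positions; 1U bias unmet",
                           label, "U" if want_t else "non-U")
            pool = np.concatenate([cand["T"], cand["other"]])
        return int(pool[rng.integers(pool.size)])

    def extract(chrom: str, p5: int, strand: str, length: int) -> str | None:
        cseq = genome[chrom]
        if strand == "+":
            if p5 + length > len(cseq):
                return None
            return cseq[p5: p5 + length]
        if p5 - length + 1 < 0:
            return None
        return revcomp(cseq[p5 - length + 1: p5 + 1])

    reads: list[str] = []
    rows: list[dict] = []

    def emit(chrom, p5, strand, label, target_gene, in_pgf, kind) -> bool:
        length = int(rng.integers(lmin, lmax + 1))
        seq = extract(chrom, p5, strand, length)
        if seq is None or "N" in seq:
            return False
        if sampling.error_rate > 0:
            arr = list(seq)
            for i in range(len(arr)):
                if rng.random() < sampling.error_rate:
                    arr[i] = _other_base(arr[i], rng)
            seq = "".join(arr)
        reads.append(seq)
        rows.append(
            {
                "read_id": f"r{len(reads)}",
                "sequence": seq,
                "chrom": chrom,
                "five_prime_pos": p5,
                "strand": strand,
                "source": label,
                "target_gene": target_gene,
                "in_pgf": in_pgf,
                "kind": kind,
            }
        )
        return True

    primary_record: list[tuple[str, int, str]] = []
    for label, n in zip(labels, counts):
        src = sources[label]
        for _ in range(int(n)):
            for _attempt in range(20):
                if src["strand_mode"] == "bidirectional":
                    strand = "+" if rng.random() < 0.5 else "-"
                elif src["strand_mode"] == "plus":
                    strand = "+"
                else:
                    strand = "-"
                p5 = draw_start(label, strand)
                if emit(src["chrom"], p5, strand, label, src["target_gene"],
                        src["in_pgf"], "primary"):
                    primary_record.append((src["chrom"], p5, strand))
                    break

    for _ in range(n_bg):
        # decide the 5'-base class once, then sample a position of that
        # class, so the marginal U1 frequency equals u1_probability
        want_t = rng.random() < sampling.u1_probability
        for _attempt in range(200):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            strand = "+" if rng.random() < 0.5 else "-"
            p5 = int(rng.integers(genome.length(chrom)))
            base = genome[chrom][p5]
            is_t = (base == "T") if strand == "+" else (base == "A")
            if is_t != want_t:
                continue
            if emit(chrom, p5, strand, "background", "", False, "background"):
                break

    for _ in range(n_pp):
        if not primary_record:
            break
        for _attempt in range(20):
            chrom, p5, strand = primary_record[int(rng.integers(len(primary_record)))]
            # responder 5' end overlaps the primary 5' end by exactly 10 nt
            if strand == "+":
                mate_p5, mate_strand = p5 + 9, "-"
            else:
                mate_p5, mate_strand = p5 - 9, "+"
            if emit(chrom, mate_p5, mate_strand, "pingpong_mate", "", False, "mate"):
                break

    truth = pd.DataFrame(rows)
    return reads, truth


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def simulate_expression(
    target_weights: dict[str, float],
    other_genes: list[str],
    cfg: ExpressionConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gene-level log2FC table with planted target upregulation.

    Genes in the cumulative-``coverage`` prefix of the planted weight
    ranking draw from Normal(effect_size_top, sd), remaining targets
    from Normal(effect_size_lower, sd), and non-targets (both annotated
    decoys and ``n_non_targets`` filler genes) from Normal(0, sd).
    padj is a Benjamini-Hochberg-adjusted one-sample z-test against 0.
    """
    ordered = sorted(target_weights.items(), key=lambda kv: (-kv[1], kv[0]))
    totw = sum(w for _, w in ordered) or 1.0
    cum = 0.0
    rows = []
    for gid, w in ordered:
        cum += w / totw
        group = "top" if cum <= cfg.coverage + 1e-12 else "lower"
        # the gene that crosses the threshold still belongs to the top set
        if group == "lower" and cum - w / totw < cfg.coverage - 1e-12:
            group = "top"
        effect = cfg.effect_size_top if group == "top" else cfg.effect_size_lower
        rows.append((gid, effect, group))
    for gid in other_genes:
        rows.append((gid, 0.0, "non"))
    for i in range(cfg.n_non_targets):
        rows.append((f"NT{i + 1:05d}", 0.0, "non"))
    log2fc = np.array([rng.normal(eff, cfg.sd) for _, eff, _ in rows])
    z = log2fc / cfg.sd
    p = 2 * stats.norm.sf(np.abs(z))
    padj = _benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "gene_id": [g for g, _, _ in rows],
            "log2fc": log2fc,
            "padj": padj,
            "planted_group": [grp for _, _, grp in rows],
        }
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(config: SimConfig | str, seed: int | None = None) -> SimResult:
    """Run the full generator for a config (named, path or object)."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    if seed is not None:
        config = replace(config, seed=int(seed))
    config = _expand_panel(config)
    rng = np.random.default_rng(config.seed)
    genome, genes, clusters, pgf_truth, sources = simulate_genome_and_annotation(
        config, rng
    )
    reads, read_truth = sample_pirnas(genome, sources, config.sampling, rng)

    emission = dict(config.sampling.emission)
    target_weights: dict[str, float] = {}
    for label, w in emission.items():
        gene = sources.get(label, {}).get("target_gene", "")
        if gene:
            target_weights[gene] = target_weights.get(gene, 0.0) + w
    other = [g.gene_id for g in genes if g.gene_id not in target_weights]
    expression = simulate_expression(target_weights, other, config.expression, rng)
    return SimResult(
        config=config,
        genome=genome,
        genes=genes,
        clusters=clusters,
        pgf_truth=pgf_truth,
        reads=reads,
        read_truth=read_truth,
        expression=expression,
        target_weights=target_weights,
    )


def validate_truth(result: SimResult) -> None:
    """Cross-check truth records against the emitted sequences.

    Raises AssertionError when a sampled read is not a genome substring
    at its recorded position, or a PGF truth interval escapes its host
    cluster.  Called by tests and on bundle export.
    """
    for row in result.read_truth.itertuples():
        cseq = result.genome[row.chrom]
        if row.strand == "+":
            expect = cseq[row.five_prime_pos: row.five_prime_pos + len(row.sequence)]
        else:
            expect = revcomp(
                cseq[row.five_prime_pos - len(row.sequence) + 1: row.five_prime_pos + 1]
            )
        if result.config.sampling.error_rate == 0:
            assert row.sequence == expect, f"read {row.read_id} not a genome substring"
    clusters = {c.cluster_id: c for c in result.clusters}
    for row in result.pgf_truth.itertuples():
        c = clusters[row.cluster_id]
        assert c.start <= row.start < row.end <= c.end, (
            f"PGF {row.pgf_id} outside host cluster"
        )
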