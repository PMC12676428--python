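import numpy as np
import pytest

from piswarm import Genome, GeneModel, build_transcript
from piswarm.simulate import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_gene(
    rng,
    chrom_seq: str | None = None,
    n_exons: int = 3,
    strand: str = "+",
    exon_len=(60, 120),
    intron_len=(40, 90),
    utr5: int = 30,
    utr3: int = 40,
    offset: int = 50,
):
    """Assemble a random gene on a random chromosome; returns (genome, gene)."""
    exons = []
    pos = offset
    for i in range(n_exons):
        el = int(rng.integers(*exon_len))
        exons.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            pos += int(rng.integers(*intron_len))
    total = pos + 50
    seq = chrom_seq or random_dna(rng, total)
    genome = Genome({"chr1": seq})
    tx_len = sum(e - s for s, e in exons)
    gene0 = GeneModel("g1", "chr1", strand, list(exons))
    tr0 = build_transcript(gene0, genome)
    cds_pos = tr0.genomic_positions[utr5: tx_len - utr3]
    gene = GeneModel(
        "g1", "chr1", strand, list(exons),
        (int(cds_pos.min()), int(cds_pos.max()) + 1),
    )
    return genome, gene


@pytest.fixture
def random_gene(rng):
    return make_random_gene(rng)
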