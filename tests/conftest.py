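import numpy as np
import pytest

from lncarray.intervals import GeneModel, GenomicInterval, ProbeRecord
from lncarray.simulate import SimulationConfig, generate_genome


SMALL_CFG = dict(
    n_chromosomes=2,
    chromosome_length=1_000_000,
    n_genes=40,
    n_noncoding_genes=8,
    probe_counts={
        "protein_coding": 60,
        "known_lncRNA": 10,
        "intronic": 80,
        "intergenic": 30,
    },
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=11, **SMALL_CFG)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return generate_genome(small_cfg)


@pytest.fixture
def toy_genes():
    """Two coding genes and one noncoding gene on chr1, one coding on chr2.

    geneA (+): exons [100,200) [500,700) [1000,1200); introns [200,500),
    [700,1000). geneB (-): exons [5000,5300) [6000,6400). ncA: exons
    [8000,8600). chr2 geneC (+): exons [100,300) [900,1100).
    """
    geneA = GeneModel(
        "geneA", "chr1", "+",
        [GenomicInterval("chr1", 100, 200, "+"),
         GenomicInterval("chr1", 500, 700, "+"),
         GenomicInterval("chr1", 1000, 1200, "+")],
        utr5=[GenomicInterval("chr1", 100, 150, "+")],
        utr3=[GenomicInterval("chr1", 1100, 1200, "+")],
    )
    geneB = GeneModel(
        "geneB", "chr1", "-",
        [GenomicInterval("chr1", 5000, 5300, "-"),
         GenomicInterval("chr1", 6000, 6400, "-")],
        utr5=[GenomicInterval("chr1", 6300, 6400, "-")],
        utr3=[GenomicInterval("chr1", 5000, 5100, "-")],
    )
    ncA = GeneModel(
        "ncA", "chr1", "+",
        [GenomicInterval("chr1", 8000, 8600, "+")],
        biotype="noncoding",
    )
    geneC = GeneModel(
        "geneC", "chr2", "+",
        [GenomicInterval("chr2", 100, 300, "+"),
         GenomicInterval("chr2", 900, 1100, "+")],
    )
    return [geneA, geneB, ncA, geneC]


def make_probe(pid, chrom, start, end, cls="intergenic", strand="+", host=""):
    return ProbeRecord(
        pid, GenomicInterval(chrom, start, end, strand), cls, host
    )
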