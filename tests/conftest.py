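import numpy as np
import pytest

from rtscan.genome import GeneModel, GenomeAnnotation
from rtscan.coverage import CoverageTrack


def make_track(chrom_sizes, arrays, total=1_000_000.0):
    """CoverageTrack from {(chrom, strand): list/array} of per-base depth."""
    data = {k: np.asarray(v, dtype=np.float32) for k, v in arrays.items()}
    return CoverageTrack(dict(chrom_sizes), total, data)


def make_gene(gid, chrom, strand, exons):
    return GeneModel(gid, chrom, strand, tuple(exons))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_annotation():
    """Two tandem '+' genes with known exon structure plus one '-' gene elsewhere.

    geneA: [1000, 5000), 3 exons; geneB: [11000, 15000), 3 exons; gap 6000.
    geneC: '-' on chr2.
    """
    genes = {
        "geneA": make_gene("geneA", "chr1", "+", [(1000, 1800), (2500, 3200), (4200, 5000)]),
        "geneB": make_gene("geneB", "chr1", "+", [(11000, 11600), (12400, 13300), (14100, 15000)]),
        "geneC": make_gene("geneC", "chr2", "-", [(20000, 20900), (21800, 22600), (23500, 24000)]),
    }
    return GenomeAnnotation(genes, {"chr1": 40000, "chr2": 40000})
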