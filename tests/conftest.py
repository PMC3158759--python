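import numpy as np
import pytest

from nucleoscape.genome_io import ChromSizes, GeneModel, ReadTag
from nucleoscape.window_profile import make_grid


@pytest.fixture
def chrom_sizes():
    return ChromSizes({"chr1": 250_000, "chr2": 100_000})


@pytest.fixture
def grid(chrom_sizes):
    return make_grid(chrom_sizes, 100_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gene(gene_id, chrom="chr1", strand="+", start=1000, end=3000, n_exons=2,
              tx_id=""):
    """Evenly split the span into alternating exon/intron blocks."""
    length = end - start
    bounds = np.linspace(0, length, 2 * n_exons, dtype=int)
    exons = tuple((start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
                  for i in range(n_exons))
    # ensure last exon reaches tx_end
    exons = exons[:-1] + ((exons[-1][0], end),)
    return GeneModel(gene_id, chrom, strand, start, end, exons, tx_id=tx_id)


@pytest.fixture
def gene_factory():
    return make_gene
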