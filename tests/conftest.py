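import numpy as np
import pandas as pd
import pytest

from methylomap.io_formats import GeneModel, SiteMatrix


@pytest.fixture
def toy_genes():
    """Two plus-strand and one minus-strand gene on two contigs."""
    return [
        GeneModel("gA", "chr1", "+", ((100, 200), (300, 400), (500, 650))),
        GeneModel("gB", "chr1", "-", ((5300, 5400), (5000, 5100))),
        GeneModel("gC", "chr2", "+", ((2000, 2101),)),
    ]


def make_sites(meth_rows, unmeth_rows, samples, chrom="chr1", start=0, step=10):
    """Build a SiteMatrix from per-site count lists (rows = sites)."""
    n = len(meth_rows)
    index = pd.MultiIndex.from_arrays(
        [np.repeat(chrom, n), start + step * np.arange(n)], names=["chrom", "pos"]
    )
    meth = pd.DataFrame(meth_rows, index=index, columns=samples, dtype=float)
    unmeth = pd.DataFrame(unmeth_rows, index=index, columns=samples, dtype=float)
    return SiteMatrix(meth, unmeth)


@pytest.fixture
def site_matrix_factory():
    return make_sites
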