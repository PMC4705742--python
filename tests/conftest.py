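import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from erable.core import GeneMatrix
from erable.distmat import DistanceMatrix
from erable.tree import parse_newick

QUARTET_NEWICK = "((A:1,B:2):3,(C:4,D:5));"


@pytest.fixture(scope="session")
def quartet():
    return parse_newick(QUARTET_NEWICK)


@pytest.fixture(scope="session")
def quartet_dm(quartet):
    return quartet.patristic_matrix()


@pytest.fixture()
def two_genes(quartet_dm):
    """The worked two-gene example: delta2 = 3 * delta1, N = (100, 100)."""
    g1 = GeneMatrix("g1", 100, quartet_dm)
    g2 = GeneMatrix("g2", 100, DistanceMatrix(quartet_dm.taxa, 3 * quartet_dm.values))
    return [g1, g2]


@pytest.fixture()
def rng():
    return np.random.default_rng(20160107)
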