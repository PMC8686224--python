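import numpy as np
import pytest
import scipy.sparse as sp

from comanifold import DataBlock, FuzzySet, MultiGraph, assemble_multigraph


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_block(rng):
    """A 30-point, 8-feature dense block."""
    return DataBlock("demo", rng.normal(size=(30, 8)), [f"g{i}" for i in range(8)])


def two_clique_graph(n_per=10, bridge=0.05):
    """Two cliques of strength 1 joined by one weak edge, as a MultiGraph."""
    n = 2 * n_per
    m = np.zeros((n, n))
    m[:n_per, :n_per] = 1.0
    m[n_per:, n_per:] = 1.0
    np.fill_diagonal(m, 0.0)
    m[0, n_per] = m[n_per, 0] = bridge
    fs_all = FuzzySet(
        sp.csr_matrix(m), ("x",), [("x", i) for i in range(n)]
    )
    return assemble_multigraph({"x": n}, {"x": fs_all})


@pytest.fixture
def clique_pair():
    return two_clique_graph()
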