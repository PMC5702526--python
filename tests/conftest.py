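import numpy as np
import pytest

from ctrlnet.atlas import pairwise_distances
from ctrlnet.datasets import (load_reference_atlas, load_reference_component,
                              reference_component_edges)


@pytest.fixture(scope="session")
def atlas():
    return load_reference_atlas()


@pytest.fixture(scope="session")
def dist_table(atlas):
    return pairwise_distances(atlas)


@pytest.fixture(scope="session")
def component_df(atlas):
    return load_reference_component(atlas)


@pytest.fixture(scope="session")
def component_edges(atlas):
    return reference_component_edges(atlas)


def random_adjacency(rng, n, p=None):
    """Random symmetric 0/1 adjacency with zero diagonal."""
    if p is None:
        p = rng.uniform(0.15, 0.7)
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    return a + a.T


@pytest.fixture(scope="session")
def small_graphs():
    """200 random graphs with up to 12 nodes (shared across oracle tests)."""
    rng = np.random.default_rng(42)
    graphs = []
    for _ in range(200):
        n = int(rng.integers(4, 13))
        graphs.append(random_adjacency(rng, n))
    return graphs
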