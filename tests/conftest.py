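import networkx as nx
import numpy as np
import pytest

from weaknodes.network import BrainNetwork
from weaknodes.synthgen import CohortSpec, generate_modular_graph

EXAMPLE3_SPEC = CohortSpec(module_sizes=(40, 15, 40), intra_density=0.2,
                           n_bridge_nodes=5, bridge_degree_cap=3, seed=1)

# sparse evoked condition: the regime where the sparsest connected network
# coincides with the planted graph (used for inference-recovery checks)
SPARSE_SPEC = CohortSpec(module_sizes=(40, 15, 40), intra_density=0.08,
                         n_bridge_nodes=5, bridge_degree_cap=3, seed=1)


def random_connected_graph(rng: np.random.Generator, n_max: int = 10,
                           n_min: int = 4) -> nx.Graph:
    """Small connected G(n, p) graph, redrawn until connected."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.25, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if n and nx.is_connected(g):
            return g


def random_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.8))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))


@pytest.fixture(scope="session")
def example3_truth():
    return generate_modular_graph(EXAMPLE3_SPEC)


@pytest.fixture(scope="session")
def sparse_truth():
    return generate_modular_graph(SPARSE_SPEC)


@pytest.fixture(scope="session")
def default_truth():
    return generate_modular_graph(CohortSpec(seed=0))


@pytest.fixture
def two_clique_bridge():
    """Two 4-cliques joined through one degree-2 bridge node (node 8)."""
    g = nx.Graph()
    for base in (0, 4):
        for i in range(base, base + 4):
            for j in range(i + 1, base + 4):
                g.add_edge(i, j)
    g.add_edge(8, 0)
    g.add_edge(8, 4)
    modules = {v: ("a" if v < 4 else "b") for v in range(8)}
    modules[8] = "bridge"
    return BrainNetwork(g, modules)
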