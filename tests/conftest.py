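import math

import networkx as nx
import numpy as np
import pytest

from sdhe import cgm, embed, npso


def random_graph(rng: np.random.Generator, n_max: int = 30, p: float = 0.3) -> nx.Graph:
    """Erdos-Renyi-ish random simple graph with string labels."""
    n = int(rng.integers(4, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(str(i) for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(str(i), str(j))
    return g


@pytest.fixture(scope="session")
def barbell_k6():
    """Two K6 cliques joined through a single degree-2 bridge node."""
    g = nx.Graph()
    a = [f"a{i}" for i in range(6)]
    b = [f"b{i}" for i in range(6)]
    for clique in (a, b):
        for i in range(6):
            for j in range(i + 1, 6):
                g.add_edge(clique[i], clique[j])
    g.add_edge("x", "a0")
    g.add_edge("x", "b0")
    return g


@pytest.fixture(scope="session")
def barbell_pipeline(barbell_k6):
    coords = embed.embed(barbell_k6, gamma=2.5, seed=0)
    assignment = cgm.critical_gap_sweep(barbell_k6, coords)
    return barbell_k6, coords, assignment


@pytest.fixture(scope="session")
def small_npso():
    """One small generated network with ground truth, shared across tests."""
    params = npso.NpsoParams(n=300, m=4, gamma=2.7, T=0.1, C=4, seed=7)
    net, truth = npso.generate(params)
    return params, net, truth


@pytest.fixture(scope="session")
def small_embedded(small_npso):
    params, net, truth = small_npso
    coords = embed.embed(net, seed=7)
    assignment = cgm.critical_gap_sweep(net, coords)
    return net, truth, coords, assignment


def two_triangles_bridge() -> nx.Graph:
    """Two triangles joined by one edge (the classic Q = 5/14 example)."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "a")])
    g.add_edges_from([("d", "e"), ("e", "f"), ("f", "d")])
    g.add_edge("a", "d")
    return g
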