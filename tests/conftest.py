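import networkx as nx
import numpy as np
import pytest

from anna.network import AnatomicalNetwork, AnatomicalNode


def make_net(edges, nodes=None, name="toy"):
    """Build a network from an edge list (and optional extra nodes)."""
    ids = []
    seen = set()
    for a, b in edges:
        for v in (a, b):
            if v not in seen:
                seen.add(v)
                ids.append(v)
    for v in nodes or []:
        if v not in seen:
            seen.add(v)
            ids.append(v)
    return AnatomicalNetwork(
        [AnatomicalNode(v) for v in ids],
        {(a, b) if a < b else (b, a) for a, b in edges},
        name=name,
    )


def from_networkx(g, name="toy"):
    ids = [f"v{i}" for i in g.nodes]
    return AnatomicalNetwork(
        [AnatomicalNode(v) for v in ids],
        {(f"v{a}", f"v{b}") for a, b in g.edges},
        name=name,
    )


def random_connected_net(rng, n_lo=4, n_hi=9, p_lo=0.3, p_hi=0.7):
    """A connected G(n, p) network with at least 2 links."""
    while True:
        n = int(rng.integers(n_lo, n_hi))
        p = float(rng.uniform(p_lo, p_hi))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        if nx.is_connected(g) and g.number_of_edges() >= 2:
            return from_networkx(g)


@pytest.fixture
def two_cliques_bridge():
    """Two 5-cliques joined by a single bridge edge (K = 21)."""
    edges = []
    for block in ("a", "b"):
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((f"{block}{i}", f"{block}{j}"))
    edges.append(("a0", "b0"))
    return make_net(edges, name="two_cliques")


@pytest.fixture
def triangle():
    return make_net([("A", "B"), ("B", "C"), ("A", "C")], name="triangle")


@pytest.fixture
def four_star():
    return make_net([("hub", "s1"), ("hub", "s2"), ("hub", "s3")], name="star")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
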