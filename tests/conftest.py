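import numpy as np
import pytest

from plexrank.graph_io import SeedSet, build_network


def random_connected_network(rng: np.random.Generator, n_max: int = 20, label: str = "A"):
    """Random connected weighted network on 3..n_max nodes (spanning tree
    plus extra random edges, uniform weights in (0.1, 2])."""
    import networkx as nx

    n = int(rng.integers(3, n_max + 1))
    g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    extra = int(rng.integers(0, n))
    nodes = list(g.nodes)
    for _ in range(extra):
        u, v = rng.choice(len(nodes), 2, replace=False)
        if u != v:
            g.add_edge(nodes[u], nodes[v])
    labels = [f"n{i:02d}" for i in range(n)]
    triples = [
        (labels[u], labels[v], float(0.1 + 1.9 * rng.random())) for u, v in g.edges
    ]
    return build_network(label, triples)


def random_network(rng: np.random.Generator, n: int, p_edge: float, label: str):
    """Random (possibly disconnected) weighted network on exactly n nodes."""
    labels = [f"n{i:02d}" for i in range(n)]
    triples = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                triples.append((labels[i], labels[j], float(0.1 + 1.9 * rng.random())))
    return build_network(label, triples, extra_nodes=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_pair():
    """Two overlapping 5-node layers plus one seed."""
    net_a = build_network(
        "A",
        [("g1", "g2", 0.9), ("g2", "g3", 0.5), ("g1", "g3", 0.4), ("g3", "g4", 0.2)],
        extra_nodes=["g5"],
    )
    net_b = build_network(
        "B",
        [("g1", "g4", 1.0), ("g4", "g5", 1.0), ("g2", "g5", 0.7)],
    )
    return net_a, net_b, SeedSet(("g1",))
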