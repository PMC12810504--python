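import networkx as nx
import pytest

from netpharm.graph_core import InteractionNetwork


def net_from(edges, nodes=()):
    return InteractionNetwork.from_edges(edges, nodes=nodes)


def adjacency(net: InteractionNetwork) -> dict:
    return {v: set(net.graph.neighbors(v)) for v in net.graph}


def random_networks(n_graphs, max_n=10, seed0=0, connected=False):
    """Seeded Erdős–Rényi test graphs with at least 2 nodes."""
    import random

    out = []
    made = 0
    seed = seed0
    while made < n_graphs:
        rng = random.Random(seed)
        n = rng.randint(2, max_n)
        p = rng.uniform(0.2, 0.8)
        g = nx.gnp_random_graph(n, p, seed=seed)
        seed += 1
        if connected and not nx.is_connected(g):
            continue
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        out.append(InteractionNetwork(g))
        made += 1
    return out


@pytest.fixture
def triangle():
    return net_from([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return net_from([("A", "B"), ("B", "C")])


@pytest.fixture
def star4():
    return net_from([("HUB", f"L{i}") for i in range(4)])
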