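import networkx as nx
import numpy as np
import pytest

from brdnet.network_core import Network


def nx_to_network(graph: nx.Graph, keep_self_loops: bool = False) -> Network:
    """Convert a networkx graph (test oracle side) into a brdnet Network."""
    net = Network(simple=not keep_self_loops)
    for node in graph.nodes:
        net.add_node(str(node))
    for a, b in graph.edges:
        if a == b and not keep_self_loops:
            continue
        net.add_edge(str(a), str(b))
    return net


def random_er_graph(rng: np.random.Generator, n_max: int = 60) -> nx.Graph:
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.05, 0.5))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


@pytest.fixture
def path3() -> Network:
    net = Network()
    net.add_edge("A", "B")
    net.add_edge("B", "C")
    return net


@pytest.fixture
def star4() -> Network:
    net = Network()
    for leaf in "BCDE":
        net.add_edge("A", leaf)
    return net


@pytest.fixture
def k4() -> Network:
    net = Network()
    nodes = "ABCD"
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            net.add_edge(a, b)
    return net


@pytest.fixture
def triangle() -> Network:
    net = Network()
    net.add_edge("A", "B")
    net.add_edge("B", "C")
    net.add_edge("A", "C")
    return net
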