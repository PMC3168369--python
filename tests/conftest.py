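import networkx as nx
import numpy as np
import pytest

from netprior.network_builder import SubNetwork, build_two_step_network


@pytest.fixture
def toy_eight_node_graph() -> nx.Graph:
    """8-protein toy graph: 1-2, 1-3, 1-4, 2-4, 3-5, 4-6, 4-7, 4-8."""
    g = nx.Graph()
    g.add_edges_from(
        [("1", "2"), ("1", "3"), ("1", "4"), ("2", "4"), ("3", "5"), ("4", "6"), ("4", "7"), ("4", "8")]
    )
    return g


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A")])
    return g


@pytest.fixture
def star4() -> nx.Graph:
    """Star with center C and leaves L1..L3."""
    g = nx.Graph()
    g.add_edges_from([("C", "L1"), ("C", "L2"), ("C", "L3")])
    return g


def random_connected_graph(n: int, rng: np.random.Generator) -> nx.Graph:
    """Small connected random graph with string labels (test helper)."""
    while True:
        g = nx.gnp_random_graph(n, min(1.0, 2.5 / max(n - 1, 1)), seed=int(rng.integers(2**31)))
        if n == 1 or nx.is_connected(g):
            break
    return nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})


def subnet_of(graph: nx.Graph, seed: str) -> SubNetwork:
    return build_two_step_network(graph, seed)
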