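import networkx as nx
import pytest


@pytest.fixture
def path4() -> nx.Graph:
    """Path 1-2-3-4 (string node labels)."""
    g = nx.Graph()
    g.add_edges_from([("1", "2"), ("2", "3"), ("3", "4")])
    return g


@pytest.fixture
def star3() -> nx.Graph:
    """Star with center C and leaves L1..L3."""
    g = nx.Graph()
    g.add_edges_from([("C", "L1"), ("C", "L2"), ("C", "L3")])
    return g


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


def random_graph(seed: int, n: int, p: float = 0.25) -> nx.Graph:
    """Seeded Erdos-Renyi graph with string labels, for oracle comparisons."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
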