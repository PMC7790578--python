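import networkx as nx
import pytest

from netpharm import load_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged 39-compound two-herb table."""
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    """The packaged 13-hub centrality table with published medians."""
    return load_fixture("table2")


@pytest.fixture()
def star5() -> nx.Graph:
    """Star K1,4 with center 'C' and leaves L1..L4."""
    g = nx.Graph()
    g.add_edges_from(("C", f"L{i}") for i in range(1, 5))
    return g


@pytest.fixture()
def k5() -> nx.Graph:
    return nx.relabel_nodes(nx.complete_graph(5), lambda i: f"N{i}")


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, lambda i: f"V{i:02d}")
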