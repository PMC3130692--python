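import networkx as nx
import numpy as np
import pytest

from pathscan import (
    PathwayGraph,
    choose_cluster_window,
    dedupe_windows,
    enumerate_windows,
    generate_random_pathway,
    truncated_distances,
)


def random_pathway_graph(n: int, p_edge: float, seed: int) -> PathwayGraph:
    """Erdős–Rényi gene network with string labels (test helper)."""
    g = nx.gnp_random_graph(n, p_edge, seed=seed)
    return PathwayGraph.from_networkx(
        nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes()}))


@pytest.fixture
def path_graph():
    """A - B - C path."""
    return PathwayGraph(edges=[("A", "B"), ("B", "C")])


@pytest.fixture
def star_graph():
    """Hub H with 4 leaves."""
    return PathwayGraph(edges=[("H", f"L{i}") for i in range(4)])


@pytest.fixture(scope="session")
def desk_pathway():
    """The desk-scale study pathway: ~300-gene scale-free network with a
    planted ~30-gene causal cluster that is exactly a circular window."""
    graph = generate_random_pathway(300, 2, seed=20260901)
    cluster = choose_cluster_window(graph, 30)
    return graph, cluster


@pytest.fixture(scope="session")
def desk_windows(desk_pathway):
    graph, _ = desk_pathway
    d = truncated_distances(graph, 4)
    return dedupe_windows(enumerate_windows(graph, d, 4))


@pytest.fixture
def rng():
    return np.random.default_rng(11)
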