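import networkx as nx
import numpy as np
import pytest

from lesmon.network import DistanceMatrix, all_pairs_shortest_paths
from lesmon.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def path_graph_dist():
    """Path A-B-C-D-E as a distance matrix."""
    g = nx.path_graph(["A", "B", "C", "D", "E"])
    return all_pairs_shortest_paths(g)


@pytest.fixture(scope="session")
def clique_dist():
    """20-clique distance matrix."""
    g = nx.complete_graph([f"P{i:02d}" for i in range(20)])
    return all_pairs_shortest_paths(g)


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted fixture shared by cheap tests."""
    spec = FixtureSpec(n_proteins=120, module_size=12, edge_p=0.03,
                       utr_length_min=100, utr_length_max=250, seed=7)
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def small_dist(small_fixture):
    return all_pairs_shortest_paths(small_fixture.network)
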