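import networkx as nx
import pytest

from pnnet import synthetic


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.make_default_spec()


@pytest.fixture(scope="session")
def true_graph(default_spec):
    """The ground-truth network structure of the default generator."""
    _, network, _ = default_spec
    G = nx.Graph()
    G.add_nodes_from(network.variable_names)
    G.add_edges_from(network.edge_set())
    return G


@pytest.fixture(scope="session")
def cohort_2000():
    """One medium synthetic cohort shared across tests."""
    return synthetic.sample_cohort(2000, seed=42)
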