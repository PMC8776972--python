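import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fdinet.fixtures import FixtureSpec, generate_drugbank_fixture, generate_foodb_fixture
from fdinet.graph_build import HomogeneousGraph


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(n_drugs=20, n_foods=8, fraction_metabolism_ddi=0.6, seed=11)


@pytest.fixture(scope="session")
def drugbank_dir(fixture_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("drugbank")
    generate_drugbank_fixture(fixture_spec, out)
    return out


@pytest.fixture(scope="session")
def foodb_dir(fixture_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("foodb")
    generate_foodb_fixture(fixture_spec, out)
    return out


def graph_from_edges(edges, nodes=None, labels=None):
    """HomogeneousGraph from [(u, v, w), ...] for scorer tests."""
    g = nx.Graph()
    for n in nodes or []:
        g.add_node(n)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, subnetwork="DD", is_bridge=False)
    for n in g.nodes:
        g.nodes[n]["kind"] = (labels or {}).get(n, "drug")
    return HomogeneousGraph(graph=g)
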