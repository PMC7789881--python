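import itertools

import networkx as nx
import pytest

from formularank import (default_formula_spec, load_formula_fixture,
                         make_toy_formula, screen_adme)


@pytest.fixture(scope="session")
def fixture_records():
    return load_formula_fixture()


@pytest.fixture(scope="session")
def fixture_screen(fixture_records):
    return screen_adme(fixture_records)


@pytest.fixture
def two_node_graph():
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0)
    return g


@pytest.fixture
def two_clique_graph():
    """Two 6-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for offset in (0, 6):
        for i, j in itertools.combinations(range(offset, offset + 6), 2):
            g.add_edge(i, j, weight=1.0)
    g.add_edge(0, 6, weight=1.0)
    return g


@pytest.fixture(scope="session")
def toy_bundle():
    return make_toy_formula(default_formula_spec(seed=11))
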