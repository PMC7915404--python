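import networkx as nx
import numpy as np
import pytest

from seirja.networks import OpinionNetwork


@pytest.fixture
def k4():
    return OpinionNetwork(nx.complete_graph(4))


@pytest.fixture
def star4():
    return OpinionNetwork(nx.star_graph(3))  # center 0, three leaves


@pytest.fixture
def triangle():
    return OpinionNetwork(nx.cycle_graph(3))


@pytest.fixture
def pair():
    g = nx.Graph()
    g.add_edge(0, 1)
    return OpinionNetwork(g)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
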