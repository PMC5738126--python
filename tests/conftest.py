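import networkx as nx
import numpy as np
import pytest

from gendernet.cohort_data import Cohort, Participant


def labeled_graph(edges, genders):
    g = nx.Graph()
    for n, gen in genders.items():
        g.add_node(n, gender=gen)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cohort():
    return Cohort(
        participants={
            "a": Participant("a", "F", {0, 1, 2, 3}),
            "b": Participant("b", "M", {0, 1, 2, 3}),
            "c": Participant("c", "F", {0}),
        },
        week_range=list(range(4)),
    )
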