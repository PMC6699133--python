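import networkx as nx
import numpy as np
import pytest

from peerspread import CohortSpec, cohort_tables
from peerspread.interventions import prepare_classes
from peerspread.network import networks_from_tables


SMALL_SPEC = CohortSpec(n_classes=4, class_size_range=(8, 14), seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across tests (4 classes)."""
    participants, nominations = cohort_tables(SMALL_SPEC)
    return participants, nominations


@pytest.fixture(scope="session")
def small_networks(small_cohort):
    participants, nominations = small_cohort
    return networks_from_tables(participants, nominations)


@pytest.fixture(scope="session")
def small_classes(small_cohort, small_networks):
    participants, _ = small_cohort
    return prepare_classes(participants, small_networks)


@pytest.fixture()
def triangle():
    """Directed 3-cycle a -> b -> c -> a with unit weights."""
    g = nx.DiGraph(class_id="tri")
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0), ("c", "a", 1.0)])
    return g


def random_digraph(rng: np.random.Generator, n: int, p: float) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v, weight=1.0)
    return g
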