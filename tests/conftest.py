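import networkx as nx
import numpy as np
import pytest

from tempat.ontology import OntologyGraph
from tempat.simulate import SimulationConfig, make_template_patterns, simulate_dataset


@pytest.fixture(scope="session")
def templates():
    return make_template_patterns(13)


@pytest.fixture(scope="session")
def default_dataset():
    """One benchmark dataset (1000 x 13, 6 clusters of 20) at a fixed seed."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def diamond():
    """D is_a B, D is_a C, B is_a A, C is_a A; plus sibling S is_a B."""
    g = nx.DiGraph()
    g.add_edges_from([("D", "B"), ("D", "C"), ("B", "A"), ("C", "A"), ("S", "B")])
    return OntologyGraph(graph=g)


def random_dag(n_terms: int, seed: int) -> OntologyGraph:
    """Random layered DAG with child->parent edges (used as a closure oracle bed)."""
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    terms = [f"T{i:03d}" for i in range(n_terms)]
    g.add_nodes_from(terms)
    for i in range(1, n_terms):
        # each term points to 1-3 earlier terms (guarantees acyclicity)
        n_parents = int(rng.integers(1, min(4, i + 1)))
        for p in rng.choice(i, size=n_parents, replace=False):
            g.add_edge(terms[i], terms[int(p)])
    return OntologyGraph(graph=g)


@pytest.fixture()
def random_dag_factory():
    return random_dag
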