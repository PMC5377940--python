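import networkx as nx
import pytest

from repairnet import GeneSetAnnotation
from repairnet.synthetic import SyntheticSpec, generate


@pytest.fixture
def small_graph():
    """5-node graph: a triangle A-B-C plus a path C-D-E."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"),
                      ("C", "D"), ("D", "E")])
    return g


@pytest.fixture
def small_annotation(small_graph):
    return GeneSetAnnotation(positives={"A", "C"})


@pytest.fixture(scope="session")
def default_dataset():
    """Default planted-module dataset, seed 1 (shared; treat as read-only)."""
    return generate(SyntheticSpec(seed=1))


def star_with_positive_leaves(n_leaves: int, n_positive: int):
    """Star network whose center has n_leaves neighbors, n_positive of
    them in the positive set."""
    g = nx.star_graph(n_leaves)
    g = nx.relabel_nodes(g, {0: "center",
                             **{i: f"leaf{i}" for i in range(1, n_leaves + 1)}})
    positives = {f"leaf{i}" for i in range(1, n_positive + 1)}
    return g, positives
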