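import numpy as np
import pytest

from netdict import Graph, path_graph


@pytest.fixture
def triangle() -> Graph:
    return Graph(edges=[("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def path3() -> Graph:
    return Graph(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def path4() -> Graph:
    return Graph(edges=[("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def four_cycle() -> Graph:
    return Graph(edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture
def star3() -> Graph:
    """Center 'c' with leaves l1..l3."""
    return Graph(edges=[("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def k4() -> Graph:
    g = Graph()
    names = ["a", "b", "c", "d"]
    for i in range(4):
        for j in range(i + 1, 4):
            g.add_edge(names[i], names[j])
    return g


def complete_graph(n: int) -> Graph:
    g = Graph(nodes=(str(i) for i in range(n)))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(str(i), str(j))
    return g


def two_patch_type_graph(n_path: int = 120, n_tri: int = 60) -> Graph:
    """Disjoint union of a long path and a chain of triangles.

    At scale k = 3 this graph has exactly two distinct mesoscale patches:
    the bare 3-chain and the 3-clique.
    """
    g = path_graph(n_path)
    for i in range(n_tri):
        a, b, c = f"t{2 * i}", f"t{2 * i + 1}", f"t{2 * i + 2}"
        g.add_edge(a, b)
        g.add_edge(b, c)
        g.add_edge(a, c)
    return g
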