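import pytest

from anna import ConnectionRecord, NodeRecord, build_network


def make_network(n_nodes, edges, tissue="bone", extra_nodes=()):
    """Small helper: nodes 1..n_nodes plus extras, all median, given edge pairs."""
    ids = list(range(1, n_nodes + 1)) + list(extra_nodes)
    nodes = [NodeRecord(i, f"unit-{i}", tissue, "median") for i in ids]
    return build_network(nodes, [ConnectionRecord(a, b) for a, b in edges])


@pytest.fixture
def triangle():
    return make_network(3, [(1, 2), (1, 3), (2, 3)])


@pytest.fixture
def path3():
    return make_network(3, [(1, 2), (2, 3)])


@pytest.fixture
def single_edge():
    return make_network(2, [(1, 2)])


@pytest.fixture
def two_triangles():
    """Two disconnected triangles {1,2,3} and {4,5,6}."""
    return make_network(6, [(1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6)])


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by the single bridge edge 3-4 (7 edges total)."""
    return make_network(
        6, [(1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6), (3, 4)]
    )


@pytest.fixture
def k5():
    return make_network(5, [(a, b) for a in range(1, 6) for b in range(a + 1, 6)])
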