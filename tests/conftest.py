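import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bridgenet import BridgeNetwork, ExpressionMatrix


def make_network(edges, nodes=()):
    """Build a BridgeNetwork from (u, v, distance[, kind]) tuples."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for edge in edges:
        u, v, d, *rest = edge
        g.add_edge(u, v, distance=float(d), kind=rest[0] if rest else "PPI")
    return BridgeNetwork(g)


def random_digraph(rng, n_nodes=None, edge_prob=0.35):
    """Random directed graph with weights in [0, 1], for oracle comparisons."""
    n = n_nodes or int(rng.integers(3, 9))
    g = nx.DiGraph()
    names = [f"N{i}" for i in range(n)]
    g.add_nodes_from(names)
    for u in names:
        for v in names:
            if u != v and rng.random() < edge_prob:
                g.add_edge(u, v, distance=float(rng.random()), kind="PPI")
    return BridgeNetwork(g)


@pytest.fixture
def chain():
    """Unit-distance chain s -> a -> t."""
    return make_network([("S", "A", 1.0), ("A", "T", 1.0)])


@pytest.fixture
def detour():
    """s -> a -> t (shortest, length 2) plus a detour s -> b -> c -> t."""
    return make_network([
        ("S", "A", 1.0), ("A", "T", 1.0),
        ("S", "B", 1.0), ("B", "C", 1.0), ("C", "T", 1.0),
    ])


@pytest.fixture
def small_expr():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0, 5.0, 5.0, 5.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    classes = pd.Series(["normal", "normal", "tumor", "tumor"], index=values.columns)
    return ExpressionMatrix(values, classes)
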