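"""Bridgeness scoring of intermediate nodes between sensor and enzyme sets.

The bridgeness of an intermediate node i, given a sensor set S and enzyme set
T on a directed weighted graph, is

    B_i = sum_{s in S} sum_{t in T} d(s, t) / d_i(s, t),

where d(s, t) is the shortest-path distance from s to t and
d_i(s, t) = d(s, i) + d(i, t) is the shortest s->t distance constrained to
pass through i.  Each addend lies in [0, 1]: it equals 1 when i sits on a
shortest s->t path and tends to 0 as i moves far away from it, so B_i is
maximal (= |S|*|T|) for a node on every sensor-enzyme shortest path.  Pairs
that cannot be connected, or cannot be connected via i, contribute 0.

The ratio addend is isolated in :func:`_addend` so an alternative functional
form (e.g. exponential decay in d_i - d) is a one-line change.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .network import BridgeNetwork

logger = logging.getLogger(__name__)

INF = math.inf


class BridgenessError(ValueError):
    pass


@dataclass
class BridgenessTable:
    """Per-gene bridgeness scores, ranks and contributing-pair counts.

    ``table`` has columns ``gene``, ``score``, ``rank``, ``n_pairs`` sorted by
    rank; ranks are 1..n with ties broken by ascending gene symbol.
    """

    table: pd.DataFrame
    n_sensors: int
    n_enzymes: int

    def top(self, k: int) -> list[str]:
        return list(self.table["gene"].iloc[:k])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _check_weights(graph: nx.DiGraph) -> None:
    for u, v, d in graph.edges(data=True):
        if d.get("distance", 1.0) < 0:
            raise BridgenessError(f"negative edge distance on {u}->{v}")


def sensor_enzyme_distances(
    network: BridgeNetwork, S: Iterable[str], T: Iterable[str]
) -> tuple[dict[str, dict[str, float]], dict[str, dict[str, float]]]:
    """Shortest-path distance maps from every sensor and to every enzyme.

    Returns ``(d_from, d_to)``: ``d_from[s]`` is the Dijkstra single-source
    map over directed weighted edges; ``d_to[t]`` the map on the
    edge-reversed graph (distance of each node *to* t).  Unreachable nodes
    are absent from the maps and read as +inf.
    """
    g = network.graph
    _check_weights(g)
    S, T = list(dict.fromkeys(S)), list(dict.fromkeys(T))
    d_from = {
        s: nx.single_source_dijkstra_path_length(g, s, weight="distance")
        for s in S if s in g
    }
    rg = g.reverse(copy=False)
    d_to = {
        t: nx.single_source_dijkstra_path_length(rg, t, weight="distance")
        for t in T if t in g
    }
    for s in S:
        d_from.setdefault(s, {})
    for t in T:
        d_to.setdefault(t, {})
    return d_from, d_to


def _addend(dst: float, d_via: float) -> float:
    """Contribution of one (s, t) pair: d(s,t) / d_i(s,t), with conventions.

    Unreachable pairs (either distance infinite) contribute 0.  A pair with
    d(s,t) = 0 and d_i(s,t) = 0 contributes 1: i coincides with a
    zero-distance (perfectly correlated) path — degenerate, capped at the
    on-path maximum.
    """
    if math.isinf(dst) or math.isinf(d_via):
        return 0.0
    if d_via == 0.0:
        if dst == 0.0:
            logger.debug("zero-distance degenerate pair; addend capped at 1")
            return 1.0
        return 0.0  # unreachable via i at zero cost cannot happen with dst > 0
    return dst / d_via


def bridgeness(
    network: BridgeNetwork,
    S: Iterable[str],
    T: Iterable[str],
    i: str,
    dist_maps: tuple[dict, dict] | None = None,
) -> float:
    """Bridgeness score B_i of intermediate node i for sensors S and enzymes T."""
    S, T = list(dict.fromkeys(S)), list(dict.fromkeys(T))
    if i in set(S) | set(T):
        raise BridgenessError(f"bridge candidates are intermediates; {i!r} is a sensor/enzyme")
    d_from, d_to = dist_maps if dist_maps is not None else sensor_enzyme_distances(network, S, T)
    total = 0.0
    for s in S:
        dsi = d_from[s].get(i, INF)
        if math.isinf(dsi):
            continue
        for t in T:
            dst = d_from[s].get(t, INF)
            dit = d_to[t].get(i, INF)
            total += _addend(dst, dsi + dit)
    return total


def rank_bridges(
    network: BridgeNetwork,
    S: Iterable[str],
    T: Iterable[str],
    k: int | None = None,
) -> BridgenessTable:
    """Score every intermediate node and return the top-k bridgeness table.

    Sorting is by descending score then ascending gene symbol (deterministic
    across runs).  ``k`` beyond the number of intermediates returns all, with
    a warning; ``k=None`` returns the full table.
    """
    S, T = list(dict.fromkeys(S)), list(dict.fromkeys(T))
    if k is not None and k < 1:
        raise BridgenessError("k must be >= 1")
    dist_maps = sensor_enzyme_distances(network, S, T)
    d_from, d_to = dist_maps
    intermediates = sorted(set(network.graph.nodes) - set(S) - set(T))
    rows = []
    for i in intermediates:
        score = 0.0
        n_pairs = 0
        for s in S:
            dsi = d_from[s].get(i, INF)
            for t in T:
                a = _addend(d_from[s].get(t, INF), dsi + d_to[t].get(i, INF))
                score += a
                n_pairs += a > 0
        rows.append((i, score, n_pairs))
    table = pd.DataFrame(rows, columns=["gene", "score", "n_pairs"])
    table = table.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    table["rank"] = range(1, len(table) + 1)
    table = table[["gene", "score", "rank", "n_pairs"]].reset_index(drop=True)
    if k is not None:
        if k > len(table):
            logger.warning("k=%d exceeds %d intermediates; returning all", k, len(table))
        table = table.head(k)
    return BridgenessTable(table, len(S), len(T))


# ---------------------------------------------------------------------------
# Brute-force oracle and comparison centralities
# ---------------------------------------------------------------------------

_BRUTE_MAX_NODES = 12


def _brute_distance(graph: nx.DiGraph, u: str, v: str) -> float:
    """Shortest u->v distance by exhaustive enumeration of simple paths.

    With non-negative weights a shortest path is always simple, so the
    minimum over simple paths equals the true shortest-path distance.
    """
    if u == v:
        return 0.0
    best = INF
    for path in nx.all_simple_paths(graph, u, v):
        w = sum(graph[a][b].get("distance", 1.0) for a, b in itertools.pairwise(path))
        best = min(best, w)
    return best


def bridgeness_bruteforce(
    network: BridgeNetwork, S: Iterable[str], T: Iterable[str], i: str
) -> float:
    """Oracle for :func:`bridgeness` on tiny graphs (<= 12 nodes): identical
    contract, but every distance comes from exhaustive simple-path enumeration."""
    g = network.graph
    if g.number_of_nodes() > _BRUTE_MAX_NODES:
        raise BridgenessError(
            f"brute-force oracle limited to {_BRUTE_MAX_NODES} nodes; got {g.number_of_nodes()}"
        )
    S, T = list(dict.fromkeys(S)), list(dict.fromkeys(T))
    if i in set(S) | set(T):
        raise BridgenessError(f"bridge candidates are intermediates; {i!r} is a sensor/enzyme")
    _check_weights(g)
    total = 0.0
    for s in S:
        if s not in g:
            continue
        for t in T:
            if t not in g or i not in g:
                continue
            dst = _brute_distance(g, s, t)
            d_via = _brute_distance(g, s, i) + _brute_distance(g, i, t)
            total += _addend(dst, d_via)
    return total


def standard_centralities(
    network: BridgeNetwork, node: str | None = None
) -> dict[str, dict[str, float]] | dict[str, float]:
    """Degree, closeness and betweenness on the directed weighted graph.

    For comparison reports only.  Closeness uses the harmonic form
    (sum of 1/d over reachable targets), which handles disconnected graphs
    without an arbitrary finite stand-in for infinite distances; betweenness
    is the unnormalized weighted shortest-path count.
    """
    g = network.graph
    degree = dict(g.degree())
    closeness = nx.harmonic_centrality(g, distance="distance")
    betweenness = nx.betweenness_centrality(g, weight="distance", normalized=False)
    out = {
        n: {"degree": float(degree[n]), "closeness": closeness[n], "betweenness": betweenness[n]}
        for n in g.nodes
    }
    return out[node] if node is not None else out
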