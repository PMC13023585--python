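"""Shared fixtures and independent brute-force oracles.

The graph oracles here deliberately avoid the package's vectorized code
paths (and scipy's graph routines): clustering by explicit neighbor-pair
enumeration, distances by a hand-rolled breadth-first search, efficiencies
by direct summation.  They exist so the implementation can be checked
against an unambiguous reference on small graphs.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from plvnet.graphmetrics import BinaryGraph


def make_graph(adjacency) -> BinaryGraph:
    adjacency = np.asarray(adjacency, dtype=int)
    return BinaryGraph([f"n{i}" for i in range(adjacency.shape[0])], adjacency)


def graph_from_edges(n: int, edges) -> BinaryGraph:
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return make_graph(adj)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def bfs_distances(adj: np.ndarray, source: int) -> list[float]:
    n = adj.shape[0]
    dist = [np.inf] * n
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u, v] and dist[v] == np.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def oracle_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        d = len(nbrs)
        if d < 2:
            continue
        links = sum(
            1
            for a in range(d)
            for b in range(a + 1, d)
            if adj[nbrs[a], nbrs[b]]
        )
        total += links / (d * (d - 1) / 2)
    return total / n


def oracle_path_length(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dists = []
    for i in range(n):
        row = bfs_distances(adj, i)
        dists.extend(row[j] for j in range(n) if j != i and np.isfinite(row[j]))
    return float(np.mean(dists)) if dists else float("nan")


def oracle_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    acc = 0.0
    for i in range(n):
        row = bfs_distances(adj, i)
        for j in range(n):
            if j != i and np.isfinite(row[j]) and row[j] > 0:
                acc += 1.0 / row[j]
    return acc / (n * (n - 1))


def oracle_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += oracle_global_efficiency(sub)
    return total / n


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def oracle_components(n_nodes: int, edges: list[tuple[int, int]]):
    """Partition edges into connected components via union-find."""
    uf = UnionFind(n_nodes)
    for i, j in edges:
        uf.union(i, j)
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, j in edges:
        comps.setdefault(uf.find(i), []).append((i, j))
    return sorted(
        (sorted(e) for e in comps.values()), key=lambda e: (-len(e), e)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
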