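"""Independent brute-force oracles for graph metrics.

Deliberately naive implementations (triangle enumeration, all-pairs BFS
by hand) kept separate from the package so metric tests compare two
independent routes.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> dict[int, int]:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in np.flatnonzero(adj[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(int(v))
    return dist


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = list(np.flatnonzero(adj[i]))
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nb, 2) if adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_path_length(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total, count = 0, 0
    for i in range(n):
        d = bfs_distances(adj, i)
        for j, dist in d.items():
            if j != i:
                total += dist
                count += 1
    if count == 0:
        raise ValueError("no reachable pairs")
    return total / count


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        d = bfs_distances(adj, i)
        for j, dist in d.items():
            if j != i:
                total += 1.0 / dist
    return total / (n * (n - 1))


def brute_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        out[i] = brute_global_efficiency(adj[np.ix_(nb, nb)])
    return out


def brute_degree(adj: np.ndarray) -> np.ndarray:
    return np.array([int(adj[i].sum()) for i in range(adj.shape[0])])


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Simple undirected G(n, p) adjacency matrix."""
    A = (rng.random((n, n)) < p).astype(np.uint8)
    A = np.triu(A, 1)
    return A + A.T
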