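"""Independent brute-force oracles for graph measures.

Deliberately naive (pure-Python BFS, explicit triangle counting, exhaustive
partition enumeration) so they share no code path with the implementation
under test.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: np.ndarray) -> dict[tuple[int, int], int]:
    n = adj.shape[0]
    dist: dict[tuple[int, int], int] = {}
    for s in range(n):
        seen = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in range(n):
                if adj[u, v] and v not in seen:
                    seen[v] = seen[u] + 1
                    queue.append(v)
        for v, d in seen.items():
            if v != s:
                dist[(s, v)] = d
    return dist


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = bfs_distances(adj)
    return sum(1.0 / d for d in dist.values()) / (n * (n - 1))


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        total += 2.0 * links / (k * (k - 1))
    return total / n


def path_length(adj: np.ndarray) -> float:
    dist = bfs_distances(adj)
    if not dist:
        raise ValueError("no connected pair")
    return sum(dist.values()) / len(dist)


def modularity_q(adj: np.ndarray, membership) -> float:
    a = adj.astype(float)
    n = a.shape[0]
    k = a.sum(axis=1)
    m2 = k.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += a[i, j] - k[i] * k[j] / m2
    return q / m2


def _set_partitions(items: list[int]):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [[first] + block] + partition[i + 1:]
        yield [[first]] + partition


def best_partition_q(adj: np.ndarray) -> float:
    """Maximum Q over all set partitions (exhaustive; n <= 8 only)."""
    n = adj.shape[0]
    best = -np.inf
    for partition in _set_partitions(list(range(n))):
        membership = np.empty(n, dtype=int)
        for label, block in enumerate(partition):
            for node in block:
                membership[node] = label
        best = max(best, modularity_q(adj, membership))
    return best


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    return adj | adj.T
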