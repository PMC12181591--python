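"""Numba kernels for the graph primitives that sit inside permutation loops.

All kernels operate on small dense graphs (the node set is the 47 cognitive
variables) and are deterministic; randomness is passed in as pre-drawn
index arrays so that a single ``numpy`` Generator controls every stochastic
choice.  Hot paths use adjacency (neighbour) lists built incrementally
along the nested density stack.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bfs_distances(A, n):
    """All-pairs unweighted shortest-path lengths; -1 for unreachable."""
    D = np.full((n, n), -1, np.int32)
    q = np.empty(n, np.int32)
    for s in range(n):
        D[s, s] = 0
        q[0] = s
        head, tail = 0, 1
        while head < tail:
            u = q[head]
            head += 1
            du = D[s, u]
            for v in range(n):
                if A[u, v] and D[s, v] < 0:
                    D[s, v] = du + 1
                    q[tail] = v
                    tail += 1
    return D


@njit(cache=True)
def distance_stats(A, n):
    """(sum of 1/d, sum of d over reachable pairs, reachable ordered pairs).

    Ordered pairs i != j; unreachable pairs contribute 0 to the inverse sum
    and are excluded from the distance sum.
    """
    D = bfs_distances(A, n)
    inv_sum = 0.0
    d_sum = 0.0
    reach = 0
    for s in range(n):
        for v in range(n):
            if v != s and D[s, v] > 0:
                inv_sum += 1.0 / D[s, v]
                d_sum += D[s, v]
                reach += 1
    return inv_sum, d_sum, reach


@njit(cache=True)
def _stats_csr(nbr, deg, n, dist, q):
    """distance_stats over adjacency lists, with caller-owned scratch."""
    inv_sum = 0.0
    d_sum = 0.0
    reach = 0
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        q[0] = s
        head, tail = 0, 1
        while head < tail:
            u = q[head]
            head += 1
            du = dist[u]
            for t in range(deg[u]):
                v = nbr[u, t]
                if dist[v] < 0:
                    dv = du + 1
                    dist[v] = dv
                    q[tail] = v
                    tail += 1
                    inv_sum += 1.0 / dv
                    d_sum += dv
                    reach += 1
    return inv_sum, d_sum, reach


@njit(cache=True)
def _clustering_csr(A, nbr, deg, n):
    total = 0.0
    for i in range(n):
        k = deg[i]
        if k < 2:
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if A[nbr[i, a], nbr[i, b]]:
                    links += 1
        total += 2.0 * links / (k * (k - 1))
    return total / n


_U1 = np.uint64(1)
_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)


@njit(cache=True)
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return int((x * _H01) >> np.uint64(56))


@njit(cache=True)
def graph_stats_bits(adj, n):
    """(mean clustering, sum 1/d, sum d over reachable pairs, reachable
    ordered pairs) for a graph given as per-node uint64 neighbour bitsets
    (n <= 64)."""
    inv_sum = 0.0
    d_sum = 0.0
    reach = 0
    c_total = 0.0
    for s in range(n):
        nbrs = adj[s]
        k = _popcount64(nbrs)
        if k >= 2:
            links = 0
            for u in range(n):
                if (nbrs >> np.uint64(u)) & _U1:
                    links += _popcount64(adj[u] & nbrs)
            c_total += links / (k * (k - 1))  # links double-counts triangles
        visited = nbrs | (_U1 << np.uint64(s))
        frontier = nbrs
        dist = 1
        cnt = _popcount64(frontier)
        while cnt > 0:
            inv_sum += cnt / dist
            d_sum += cnt * dist
            reach += cnt
            nxt = np.uint64(0)
            for u in range(n):
                if (frontier >> np.uint64(u)) & _U1:
                    nxt |= adj[u]
            nxt &= ~visited
            visited |= nxt
            frontier = nxt
            dist += 1
            cnt = _popcount64(frontier)
    return c_total / n, inv_sum, d_sum, reach


@njit(cache=True)
def adjacency_to_bits(A, n):
    adj = np.zeros(n, np.uint64)
    for i in range(n):
        m = np.uint64(0)
        for j in range(n):
            if A[i, j]:
                m |= _U1 << np.uint64(j)
        adj[i] = m
    return adj


@njit(cache=True)
def efficiency_curve_bits(ei, ej, ks, n):
    """Global efficiency along a nested stack via bit-parallel BFS (n <= 64)."""
    nd = ks.shape[0]
    out = np.empty(nd, np.float64)
    adj = np.zeros(n, np.uint64)
    prev = 0
    denom = n * (n - 1)
    for d in range(nd):
        for t in range(prev, ks[d]):
            u, v = ei[t], ej[t]
            adj[u] |= _U1 << np.uint64(v)
            adj[v] |= _U1 << np.uint64(u)
        prev = ks[d]
        inv_sum = 0.0
        for s in range(n):
            visited = adj[s] | (_U1 << np.uint64(s))
            frontier = adj[s]
            dist = 1
            cnt = _popcount64(frontier)
            while cnt > 0:
                inv_sum += cnt / dist
                nxt = np.uint64(0)
                for u in range(n):
                    if (frontier >> np.uint64(u)) & _U1:
                        nxt |= adj[u]
                nxt &= ~visited
                visited |= nxt
                frontier = nxt
                dist += 1
                cnt = _popcount64(frontier)
        out[d] = inv_sum / denom
    return out


@njit(cache=True)
def _xorshift64(s):
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    return s


@njit(cache=True)
def sigma_reference_stats(ei, ej, n, ensemble, swaps_per_edge, seed):
    """Mean clustering and path length over a degree-preserving rewired
    ensemble (n <= 64); returns (C_rand, L_rand, accepted swap count).

    Randomness comes from an inline xorshift64* generator seeded with
    ``seed`` — deterministic and platform-independent.
    """
    E = ei.shape[0]
    attempts = swaps_per_edge * E
    c_sum = 0.0
    l_sum = 0.0
    l_cnt = 0
    swaps = 0
    A = np.empty((n, n), np.bool_)
    e1 = np.empty(E, np.int32)
    e2 = np.empty(E, np.int32)
    mult = np.uint64(0x2545F4914F6CDD1D)
    state = (np.uint64(seed) + np.uint64(1)) * np.uint64(6364136223846793005)
    uE = np.uint64(E)
    for r in range(ensemble):
        for k in range(E):
            e1[k] = ei[k]
            e2[k] = ej[k]
        for i in range(n):
            for j in range(n):
                A[i, j] = False
        for k in range(E):
            A[e1[k], e2[k]] = True
            A[e2[k], e1[k]] = True
        for t in range(attempts):
            state = _xorshift64(state)
            v1 = state * mult
            state = _xorshift64(state)
            v2 = state * mult
            a = int(v1 % uE)
            b = int(v2 % uE)
            flip = int(v2 >> np.uint64(63))
            if a == b:
                continue
            u, v = e1[a], e2[a]
            x, y = e1[b], e2[b]
            if flip == 1:
                x, y = y, x
            if u == x or u == y or v == x or v == y:
                continue
            if A[u, x] or A[v, y]:
                continue
            A[u, v] = False
            A[v, u] = False
            A[x, y] = False
            A[y, x] = False
            A[u, x] = True
            A[x, u] = True
            A[v, y] = True
            A[y, v] = True
            e1[a], e2[a] = u, x
            e1[b], e2[b] = v, y
            swaps += 1
        adj = adjacency_to_bits(A, n)
        c, _, d_sum, reach = graph_stats_bits(adj, n)
        c_sum += c
        if reach > 0:
            l_sum += d_sum / reach
            l_cnt += 1
    c_mean = c_sum / ensemble
    l_mean = l_sum / l_cnt if l_cnt > 0 else np.nan
    return c_mean, l_mean, swaps


@njit(cache=True)
def efficiency_curve(ei, ej, ks, n):
    """Global efficiency at each cumulative edge count of a nested stack.

    ``ei, ej`` list edges in decreasing-weight order; ``ks`` is the
    non-decreasing sequence of edge counts (one per target density).
    """
    nd = ks.shape[0]
    out = np.empty(nd, np.float64)
    nbr = np.empty((n, n), np.int32)
    deg = np.zeros(n, np.int32)
    dist = np.empty(n, np.int32)
    q = np.empty(n, np.int32)
    prev = 0
    denom = n * (n - 1)
    for d in range(nd):
        for t in range(prev, ks[d]):
            u, v = ei[t], ej[t]
            nbr[u, deg[u]] = v
            deg[u] += 1
            nbr[v, deg[v]] = u
            deg[v] += 1
        prev = ks[d]
        inv_sum, _, _ = _stats_csr(nbr, deg, n, dist, q)
        out[d] = inv_sum / denom
    return out


@njit(cache=True)
def clustering_coefficient(A, n):
    """Mean over nodes of the local clustering coefficient (0 if degree < 2)."""
    total = 0.0
    nbrs = np.empty(n, np.int32)
    for i in range(n):
        deg = 0
        for j in range(n):
            if A[i, j]:
                nbrs[deg] = j
                deg += 1
        if deg < 2:
            continue
        links = 0
        for a in range(deg):
            for b in range(a + 1, deg):
                if A[nbrs[a], nbrs[b]]:
                    links += 1
        total += 2.0 * links / (deg * (deg - 1))
    return total / n


@njit(cache=True)
def local_efficiency(A, n):
    """Mean over nodes of the global efficiency of the neighbour-induced
    subgraph (0 for degree < 2)."""
    total = 0.0
    nbrs = np.empty(n, np.int32)
    for i in range(n):
        deg = 0
        for j in range(n):
            if A[i, j]:
                nbrs[deg] = j
                deg += 1
        if deg < 2:
            continue
        sub = np.zeros((deg, deg), np.bool_)
        for a in range(deg):
            for b in range(deg):
                sub[a, b] = A[nbrs[a], nbrs[b]]
        inv_sum, _, _ = distance_stats(sub, deg)
        total += inv_sum / (deg * (deg - 1))
    return total / n


@njit(cache=True)
def rewire_edges(ei, ej, n, pick_a, pick_b, flip):
    """Degree-preserving double-edge swaps (Maslov–Sneppen).

    ``pick_a``, ``pick_b`` index the two candidate edges per attempt and
    ``flip`` chooses the swap orientation; all are pre-drawn.  Invalid
    proposals (shared endpoints, existing target edges) are skipped, so
    degrees, edge count and simplicity are preserved exactly.  Returns the
    number of accepted swaps; ``ei, ej`` are modified in place.
    """
    E = ei.shape[0]
    A = np.zeros((n, n), np.bool_)
    for k in range(E):
        A[ei[k], ej[k]] = True
        A[ej[k], ei[k]] = True
    accepted = 0
    for t in range(pick_a.shape[0]):
        a = pick_a[t]
        b = pick_b[t]
        if a == b:
            continue
        u, v = ei[a], ej[a]
        x, y = ei[b], ej[b]
        if flip[t]:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if A[u, x] or A[v, y]:
            continue
        A[u, v] = False
        A[v, u] = False
        A[x, y] = False
        A[y, x] = False
        A[u, x] = True
        A[x, u] = True
        A[v, y] = True
        A[y, v] = True
        ei[a], ej[a] = u, x
        ei[b], ej[b] = v, y
        accepted += 1
    return accepted


@njit(cache=True)
def sigma_ensemble(ei, ej, n, pick_a, pick_b, flip):
    """Clustering and path-length means over a rewired-reference ensemble.

    ``pick_a/pick_b/flip`` have shape (ensemble, attempts).  Returns
    (mean C_rand, mean L_rand over references with any connected pair,
    total accepted swaps).
    """
    ensemble = pick_a.shape[0]
    E = ei.shape[0]
    c_sum = 0.0
    l_sum = 0.0
    l_cnt = 0
    swaps = 0
    nbr = np.empty((n, n), np.int32)
    deg = np.empty(n, np.int32)
    dist = np.empty(n, np.int32)
    q = np.empty(n, np.int32)
    A = np.empty((n, n), np.bool_)
    for r in range(ensemble):
        e1 = ei.copy()
        e2 = ej.copy()
        swaps += rewire_edges(e1, e2, n, pick_a[r], pick_b[r], flip[r])
        for i in range(n):
            deg[i] = 0
            for j in range(n):
                A[i, j] = False
        for k in range(E):
            u, v = e1[k], e2[k]
            A[u, v] = True
            A[v, u] = True
            nbr[u, deg[u]] = v
            deg[u] += 1
            nbr[v, deg[v]] = u
            deg[v] += 1
        c_sum += _clustering_csr(A, nbr, deg, n)
        _, d_sum, reach = _stats_csr(nbr, deg, n, dist, q)
        if reach > 0:
            l_sum += d_sum / reach
            l_cnt += 1
    c_mean = c_sum / ensemble
    l_mean = l_sum / l_cnt if l_cnt > 0 else np.nan
    return c_mean, l_mean, swaps


@njit(cache=True)
def connected(A, n):
    """True when the graph spans a single component over all n nodes."""
    dist = np.full(n, -1, np.int32)
    q = np.empty(n, np.int32)
    dist[0] = 0
    q[0] = 0
    head, tail = 0, 1
    seen = 1
    while head < tail:
        u = q[head]
        head += 1
        for v in range(n):
            if A[u, v] and dist[v] < 0:
                dist[v] = dist[u] + 1
                q[tail] = v
                tail += 1
                seen += 1
    return seen == n
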