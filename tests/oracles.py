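"""Independent brute-force reference implementations.

Everything here is deliberately written from the definitions, with no
shared code with the package: Floyd–Warshall distances, definitional
efficiencies, exhaustive triangle counts, explicit shortest-path
enumeration for betweenness, per-pair BFS for inter-system efficiency,
and exhaustive set-partition search for modularity.  They are only ever
run on tiny graphs.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


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


def triangles_per_node(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    t = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if j < k and adj[i, j] and adj[i, k] and adj[j, k]:
                    t[i] += 1
    return t


def clustering(adj: np.ndarray) -> np.ndarray:
    k = adj.sum(axis=1)
    t = triangles_per_node(adj)
    c = np.zeros(len(k), dtype=float)
    for i in range(len(k)):
        if k[i] >= 2:
            c[i] = 2.0 * t[i] / (k[i] * (k[i] - 1))
    return c


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest s-t path, by BFS layering + backtracking."""
    n = adj.shape[0]
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u, v] and v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if t not in dist:
        return []
    paths = []

    def back(node, path):
        if node == s:
            paths.append(tuple(reversed(path + [s])))
            return
        for u in range(n):
            if adj[u, node] and dist.get(u, -1) == dist[node] - 1:
                back(u, path + [node])

    back(t, [])
    return paths


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Fractional shortest-path counts through each node (unordered pairs)."""
    n = adj.shape[0]
    b = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for p in paths:
            for node in p[1:-1]:
                b[node] += 1.0 / len(paths)
    return b


def internetwork_inverse_l(adj: np.ndarray, idx_a, idx_b) -> float:
    """Mean 1/d over cross pairs inside the union-induced subgraph."""
    union = list(idx_a) + list(idx_b)
    sub = adj[np.ix_(union, union)]
    d = floyd_warshall(sub)
    na = len(idx_a)
    total = 0.0
    count = 0
    for i in range(na):
        for j in range(na, len(union)):
            count += 1
            if np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / count


def set_partitions(items: list[int]):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def newman_q(adj: np.ndarray, blocks: list[list[int]]) -> float:
    m2 = adj.sum()  # 2 * edge count
    q = 0.0
    for block in blocks:
        idx = np.ix_(block, block)
        e_mm = adj[idx].sum() / m2
        a_m = adj[block, :].sum() / m2
        q += e_mm - a_m**2
    return q


def best_partition_exhaustive(adj: np.ndarray) -> tuple[float, list[list[int]]]:
    best_q, best = -np.inf, None
    for part in set_partitions(list(range(adj.shape[0]))):
        q = newman_q(adj, part)
        if q > best_q:
            best_q, best = q, part
    return best_q, best


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    return adj
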