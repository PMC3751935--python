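"""Graph-theoretic statistics on binarized covariance networks.

All networks here are undirected, unweighted and defined on a fixed node
set (regions), so distances are shortest-path hop counts.  The statistics
implemented are the standard binary-graph measures used for covariance
networks: global efficiency E_glob (integration), local efficiency E_loc
(segregation), per-node degree K_i, clustering C_i, betweenness b_i with
mean-normalized B_i, the hierarchy exponent beta of the power law
C = k^-beta, Newman modularity Q with a seeded Louvain partition, and the
module-role measures P_i (participation coefficient) and Z_i
(within-module degree z-score).

Hot-path helpers that operate on a raw adjacency array (prefixed ``_``)
exist because the permutation test recomputes these statistics thousands
of times; the public functions take a :class:`BinaryNetwork` and are the
documented surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import BinaryNetwork

__all__ = [
    "Partition",
    "HierarchyFit",
    "MetricError",
    "shortest_path_matrix",
    "global_efficiency",
    "local_efficiency",
    "degree_and_clustering",
    "betweenness",
    "fit_hierarchy_exponent",
    "modularity_partition",
    "module_roles",
    "compute_node_metrics",
]


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class Partition:
    """Non-overlapping module assignment with its modularity score."""

    labels: np.ndarray  # module id per node, 0..n_modules-1
    q: float
    n_modules: int

    def modules(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == m) for m in range(self.n_modules)]


@dataclass(frozen=True)
class HierarchyFit:
    """Power-law fit C = k^-beta on log–log axes."""

    beta: float
    intercept: float
    n_points: int
    r_squared: float


# ---------------------------------------------------------------------------
# array-level kernels

def _hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop counts; unreachable pairs are ``inf``.

    Level-synchronous BFS from all sources at once via boolean matrix
    powers: after t multiplications ``reach`` holds the pairs within
    t+1 hops, so each iteration labels one distance shell.  Exact for
    unweighted graphs; O(diameter * n^3) bit-ops, which beats per-source
    BFS comfortably at the matrix sizes used here.
    """
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    if n == 1:
        return d
    step = adj.astype(bool)
    np.fill_diagonal(step, True)
    d[adj > 0] = 1.0
    reach = step.copy()
    dist = 1
    while True:
        new = reach @ step
        newly = new & ~reach
        if not newly.any():
            return d
        dist += 1
        d[newly] = dist
        reach = new


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        raise MetricError("global efficiency needs at least 2 nodes")
    d = _hop_distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        raise MetricError("local efficiency needs at least 2 nodes")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        total += _global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / n


def _degree_clustering(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = adj.sum(axis=1).astype(float)
    a = adj.astype(float)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return k, c


def _hierarchy_points(adj: np.ndarray) -> np.ndarray:
    k, c = _degree_clustering(adj)
    ok = (k >= 2) & (c > 0)
    return np.column_stack([k[ok], c[ok]])


# ---------------------------------------------------------------------------
# public surface

def shortest_path_matrix(net: BinaryNetwork) -> np.ndarray:
    """Hop-count shortest paths between all region pairs (inf = unreachable)."""
    return _hop_distances(net.adjacency)


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse shortest path length over ordered node pairs, 1/inf = 0."""
    return _global_efficiency(net.adjacency)


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph.

    Nodes with fewer than two neighbors contribute 0.
    """
    return _local_efficiency(net.adjacency)


def degree_and_clustering(net: BinaryNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node degree K_i and clustering coefficient C_i (0 when K_i < 2)."""
    return _degree_clustering(net.adjacency)


def betweenness(net: BinaryNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Raw betweenness b_i (fractional over tied shortest paths) and B_i.

    b_i counts, for every unordered pair (s, t) with s != i != t, the
    fraction of shortest s–t paths passing through i (Brandes counting).
    B_i = b_i / mean(b); when every b_i is 0 (e.g. a complete graph),
    B_i is defined as 0 everywhere.
    """
    g = net.to_networkx()
    raw = nx.betweenness_centrality(g, normalized=False)
    b = np.array([raw[i] for i in range(net.n_nodes)], dtype=float)
    mean_b = b.mean()
    bn = b / mean_b if mean_b > 0 else np.zeros_like(b)
    return b, bn


def fit_hierarchy_exponent(points: np.ndarray) -> HierarchyFit:
    """Fit C = k^-beta by OLS of log C on log K.

    ``points`` is an array of (K_i, C_i) rows; only nodes with K_i >= 2
    and C_i > 0 enter the fit (the log is undefined otherwise).  beta is
    minus the fitted slope, so beta > 0 means clustering falls with
    degree — the signature of hierarchical organization.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise MetricError("points must be an array of (K, C) rows")
    ok = (pts[:, 0] >= 2) & (pts[:, 1] > 0)
    pts = pts[ok]
    if pts.shape[0] < 2 or np.unique(pts[:, 0]).size < 2:
        raise MetricError(
            "hierarchy fit needs >= 2 eligible nodes (K >= 2, C > 0) "
            "with distinct degrees"
        )
    x = np.log(pts[:, 0])
    y = np.log(pts[:, 1])
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return HierarchyFit(
        beta=float(-slope),
        intercept=float(intercept),
        n_points=int(pts.shape[0]),
        r_squared=r2,
    )


def _hierarchy_beta(adj: np.ndarray) -> float:
    """Hot-path beta; NaN when the fit is degenerate."""
    try:
        return fit_hierarchy_exponent(np.column_stack(_degree_clustering(adj))).beta
    except MetricError:
        return float("nan")


def modularity_partition(net: BinaryNetwork, seed: int = 0) -> Partition:
    """Louvain community structure maximizing Newman modularity Q.

    Deterministic given ``seed`` and the node order.  Q is computed for
    the returned partition with the standard null model
    Q = sum_m (e_mm - a_m^2).
    """
    if net.edge_count == 0:
        raise MetricError("modularity is undefined for an edgeless graph")
    g = net.to_networkx()
    communities = nx.community.louvain_communities(g, seed=seed)
    # stable module numbering: by smallest member index
    communities = sorted(communities, key=min)
    labels = np.empty(net.n_nodes, dtype=int)
    for m, members in enumerate(communities):
        labels[list(members)] = m
    q = nx.community.modularity(g, communities)
    return Partition(labels=labels, q=float(q), n_modules=len(communities))


def module_roles(
    net: BinaryNetwork, partition: Partition
) -> tuple[np.ndarray, np.ndarray]:
    """Participation coefficient P_i and within-module degree z-score Z_i.

    P_i = 1 - sum_m (K_im / K_i)^2 (0 for isolated nodes); Z_i
    standardizes each node's within-module degree against its own
    module's mean and (population) SD, with Z_i = 0 where the SD is 0.
    """
    adj = net.adjacency
    n = net.n_nodes
    labels = np.asarray(partition.labels)
    if labels.shape != (n,):
        raise MetricError("partition does not cover the node set")
    k = adj.sum(axis=1).astype(float)
    # per-node degree into each module
    n_mod = int(labels.max()) + 1
    member = np.zeros((n, n_mod))
    member[np.arange(n), labels] = 1.0
    k_im = adj @ member  # n x n_mod
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, k_im / k[:, None], 0.0)
    p = np.where(k > 0, 1.0 - (frac**2).sum(axis=1), 0.0)

    k_within = k_im[np.arange(n), labels]
    z = np.zeros(n)
    for m in range(n_mod):
        idx = labels == m
        mu = k_within[idx].mean()
        sd = k_within[idx].std()
        if sd > 0:
            z[idx] = (k_within[idx] - mu) / sd
    return p, z


def compute_node_metrics(
    net: BinaryNetwork, partition: Partition | None = None, seed: int = 0
) -> pd.DataFrame:
    """All per-node statistics as one table.

    Columns: ``region K C b B P Z module``.  When ``partition`` is None a
    Louvain partition is computed with ``seed``; for an edgeless graph
    P = Z = 0 and module = 0.
    """
    k, c = degree_and_clustering(net)
    b, bn = betweenness(net)
    if partition is None and net.edge_count > 0:
        partition = modularity_partition(net, seed=seed)
    if partition is None:
        p = np.zeros(net.n_nodes)
        z = np.zeros(net.n_nodes)
        module = np.zeros(net.n_nodes, dtype=int)
    else:
        p, z = module_roles(net, partition)
        module = partition.labels
    labels = net.region_labels or [str(i) for i in range(net.n_nodes)]
    return pd.DataFrame(
        {
            "region": labels,
            "K": k,
            "C": c,
            "b": b,
            "B": bn,
            "P": p,
            "Z": z,
            "module": module,
        }
    )
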