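"""Subsystem-level integration and hub characterization.

Inter-network efficiency between two functional subsystems is the mean
inverse shortest path length (1/L) over cross-system region pairs,
computed on the subgraph induced by the union of the two systems — paths
may not detour through third systems.

Hubs are regions with normalized betweenness B_i > 1.5 and degree above
the network mean; hubs with below-average clustering sit at a
hierarchically *high* level (they bridge rather than cluster), the rest
at a low level.  With a module partition in hand, nodes are further
classified by participation coefficient and within-module degree into
connector/provincial hubs and nodes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import MetricError, _global_efficiency, _hop_distances, compute_node_metrics
from .network import BinaryNetwork
from .parcellation import ParcellationMap

__all__ = [
    "internetwork_efficiency",
    "identify_hubs",
    "classify_connector_nodes",
    "hub_table",
    "DEFAULT_P_THRESHOLD",
    "DEFAULT_Z_THRESHOLD",
    "HUB_BETWEENNESS_THRESHOLD",
]

#: Hub rule: normalized betweenness must exceed this multiple of the mean.
HUB_BETWEENNESS_THRESHOLD = 1.5
#: Connector/provincial split on the participation coefficient.
DEFAULT_P_THRESHOLD = 0.05
#: Hub/non-hub split on the within-module degree z-score.
DEFAULT_Z_THRESHOLD = 1.0


def _internetwork_from_adjacency(
    adj: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> float:
    union = np.concatenate([idx_a, idx_b])
    sub = adj[np.ix_(union, union)]
    d = _hop_distances(sub)
    na = idx_a.size
    cross = d[:na, na:]
    with np.errstate(divide="ignore"):
        inv = 1.0 / cross
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def internetwork_efficiency(
    net: BinaryNetwork, pmap: ParcellationMap, system_a: str, system_b: str
) -> float:
    """Average inverse shortest path length between two subsystems.

    Distances come from the subgraph induced by the union of the two
    systems' regions; the mean runs over cross-system pairs only, with
    1/inf = 0 for unreachable pairs.
    """
    if system_a == system_b:
        raise MetricError("inter-network efficiency needs two distinct subsystems")
    idx_a = np.asarray(pmap.subsystem_members(system_a))
    idx_b = np.asarray(pmap.subsystem_members(system_b))
    if net.n_nodes != pmap.n_regions:
        raise MetricError(
            f"network has {net.n_nodes} nodes but parcellation has "
            f"{pmap.n_regions} regions"
        )
    return _internetwork_from_adjacency(net.adjacency, idx_a, idx_b)


def identify_hubs(node_metrics: pd.DataFrame) -> pd.DataFrame:
    """Flag hub regions and their hierarchical level.

    Adds ``is_hub`` (B > 1.5 and K > mean K, means over all nodes) and
    ``level`` in {high, low, none}: a hub with clustering below the
    network mean is hierarchically high, otherwise low.
    """
    out = node_metrics.copy()
    mean_k = out["K"].mean()
    mean_c = out["C"].mean()
    out["is_hub"] = (out["B"] > HUB_BETWEENNESS_THRESHOLD) & (out["K"] > mean_k)
    level = np.where(out["C"] < mean_c, "high", "low")
    out["level"] = np.where(out["is_hub"], level, "none")
    return out


def classify_connector_nodes(
    node_metrics: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Connector/provincial classification from P_i and Z_i.

    Z > z_threshold marks module hubs; P > p_threshold marks connectors:
    connector_hub, provincial_hub, connector_node, provincial_node.
    """
    out = node_metrics.copy()
    is_connector = out["P"] > p_threshold
    is_module_hub = out["Z"] > z_threshold
    cls = np.where(
        is_module_hub,
        np.where(is_connector, "connector_hub", "provincial_hub"),
        np.where(is_connector, "connector_node", "provincial_node"),
    )
    out["connector_class"] = cls
    return out


def hub_table(
    net: BinaryNetwork,
    seed: int = 0,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Full per-region hub characterization at one sparsity.

    Convenience wrapper: node metrics (with a seeded module partition),
    hub identification and connector classification in one table with
    columns ``region K B C P Z module is_hub level connector_class``.
    """
    m = compute_node_metrics(net, seed=seed)
    m = identify_hubs(m)
    m = classify_connector_nodes(m, p_threshold, z_threshold)
    return m[
        ["region", "K", "B", "C", "P", "Z", "module", "is_hub", "level", "connector_class"]
    ]
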