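"""Permutation-based group inference across the sparsity grid.

Because a covariance network is a *group-level* object (one correlation
matrix per group, not per subject), group differences in its topology
cannot be tested subject-wise.  Inference is by permutation of group
labels: subjects are randomly reassigned to two groups of the original
sizes, and the entire construction — covariate residualization, partial
correlation, binarization at each sparsity, metric evaluation — is
recomputed for every relabeling.  The observed difference is compared
with the permutation null; the 95th percentile of the null in the tested
tail is the one-tailed critical value, and the p-value uses the add-one
estimator p = (1 + #{null at least as extreme}) / (n_perm + 1).

Covariates travel with subjects (labels permute, age/sex do not), so the
adjustment is honestly re-applied inside every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .metrics import (
    _global_efficiency,
    _hierarchy_beta,
    _local_efficiency,
)
from .network import (
    CovariateTable,
    NetworkConstructionError,
    ThicknessMatrix,
    ranked_pair_order,
    target_edges,
)
from .parcellation import ParcellationMap
from .subsystems import _internetwork_from_adjacency

__all__ = [
    "SparsityGrid",
    "Metric",
    "make_metric",
    "PermutationResult",
    "group_metric_curves",
    "permutation_test",
]

TAILS = ("greater", "less")


@dataclass(frozen=True)
class SparsityGrid:
    """Evenly spaced sparsity levels (defaults 0.07..0.40 step 0.01)."""

    s_min: float = 0.07
    s_max: float = 0.40
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.s_min <= self.s_max <= 1):
            raise ValueError(f"invalid sparsity bounds [{self.s_min}, {self.s_max}]")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def levels(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        return np.round(self.s_min + self.step * np.arange(n), 10)

    def __len__(self) -> int:
        return self.levels().size

    def __contains__(self, s: float) -> bool:
        return bool(np.any(np.isclose(self.levels(), s)))


@dataclass(frozen=True)
class Metric:
    """A named scalar network statistic evaluated on an adjacency array."""

    name: str
    evaluate: Callable[[np.ndarray], float]


def make_metric(name: str, pmap: ParcellationMap | None = None) -> Metric:
    """Resolve a metric by name.

    Recognized: ``E_glob``, ``E_loc``, ``beta``, and
    ``internetwork:<system_a>:<system_b>`` (requires ``pmap``).
    """
    if name == "E_glob":
        return Metric("E_glob", _global_efficiency)
    if name == "E_loc":
        return Metric("E_loc", _local_efficiency)
    if name == "beta":
        return Metric("beta", _hierarchy_beta)
    if name.startswith("internetwork:"):
        parts = name.split(":")
        if len(parts) != 3:
            raise ValueError(
                "internetwork metric must be 'internetwork:<system_a>:<system_b>'"
            )
        if pmap is None:
            raise ValueError("internetwork metric needs a ParcellationMap")
        _, a, b = parts
        idx_a = np.asarray(pmap.subsystem_members(a))
        idx_b = np.asarray(pmap.subsystem_members(b))
        return Metric(name, lambda adj: _internetwork_from_adjacency(adj, idx_a, idx_b))
    raise ValueError(f"unknown metric {name!r}")


@dataclass
class PermutationResult:
    """Per-sparsity observed differences against the permutation null."""

    table: pd.DataFrame  # sparsity, group1_value, group2_value, diff,
    #                      null_mean, crit95, p, significant
    metric: str
    n_permutations: int
    seed: int
    tail: str
    null_diffs: np.ndarray = field(repr=False)  # n_perm x n_levels


# ---------------------------------------------------------------------------
# fast recompute path (raw arrays; no per-iteration object construction)

def _residualize_rows(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of every column of ``values`` on ``design``.

    Columns of the design that are constant within this subject subset
    (a permuted group can end up single-sex) are absorbed by the
    intercept and dropped.
    """
    keep = [0] + [j for j in range(1, design.shape[1]) if np.ptp(design[:, j]) > 0]
    x = design[:, keep]
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def _corr_of_residuals(resid: np.ndarray) -> np.ndarray:
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        raise NetworkConstructionError(
            "zero residual variance; correlation undefined"
        )
    r = np.corrcoef(resid, rowvar=False)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def _metric_curve(
    corr: np.ndarray,
    edge_counts: np.ndarray,
    metric: Metric,
    iu: np.ndarray,
    ju: np.ndarray,
    ranking: str,
) -> np.ndarray:
    """Evaluate a metric at nested sparsity levels from one ranking pass.

    Edge sets across the grid are nested under a fixed ranking, so the
    adjacency is grown incrementally instead of rebuilt per level.
    """
    order = ranked_pair_order(corr, ranking)
    n = corr.shape[0]
    adj = np.zeros((n, n), dtype=np.int8)
    out = np.empty(edge_counts.size)
    prev = 0
    for idx, m in enumerate(edge_counts):
        sel = order[prev:m]
        adj[iu[sel], ju[sel]] = 1
        adj[ju[sel], iu[sel]] = 1
        prev = m
        out[idx] = metric.evaluate(adj)
    return out


def _curves_for_split(
    values: np.ndarray,
    design: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    edge_counts: np.ndarray,
    metric: Metric,
    iu: np.ndarray,
    ju: np.ndarray,
    ranking: str,
) -> tuple[np.ndarray, np.ndarray]:
    corr_a = _corr_of_residuals(_residualize_rows(values[idx_a], design[idx_a]))
    corr_b = _corr_of_residuals(_residualize_rows(values[idx_b], design[idx_b]))
    va = _metric_curve(corr_a, edge_counts, metric, iu, ju, ranking)
    vb = _metric_curve(corr_b, edge_counts, metric, iu, ju, ranking)
    return va, vb


def _pool(
    thickness_a: ThicknessMatrix,
    thickness_b: ThicknessMatrix,
    covariates: CovariateTable,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    if thickness_a.region_labels != thickness_b.region_labels:
        raise NetworkConstructionError("groups have different region columns")
    cov_a = covariates.subset(thickness_a.subject_ids)
    cov_b = covariates.subset(thickness_b.subject_ids)
    values = np.vstack([thickness_a.values, thickness_b.values])
    design = np.vstack([cov_a.design_matrix(), cov_b.design_matrix()])
    return values, design, thickness_a.n_subjects, thickness_b.n_subjects


# ---------------------------------------------------------------------------
# public surface

def group_metric_curves(
    thickness_a: ThicknessMatrix,
    thickness_b: ThicknessMatrix,
    covariates: CovariateTable,
    grid: SparsityGrid,
    metric: Metric | str,
    pmap: ParcellationMap | None = None,
    ranking: str = "signed",
) -> pd.DataFrame:
    """Evaluate a network statistic for both groups across the grid.

    Returns a table with columns ``sparsity, group1_value, group2_value,
    diff`` (diff = group1 - group2).  A level where the metric is
    undefined (e.g. a degenerate hierarchy fit) is recorded as NaN.
    """
    if isinstance(metric, str):
        metric = make_metric(metric, pmap)
    values, design, n_a, n_b = _pool(thickness_a, thickness_b, covariates)
    n_regions = values.shape[1]
    levels = grid.levels()
    edge_counts = np.array([target_edges(s, n_regions) for s in levels])
    iu, ju = np.triu_indices(n_regions, k=1)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)
    va, vb = _curves_for_split(
        values, design, idx_a, idx_b, edge_counts, metric, iu, ju, ranking
    )
    return pd.DataFrame(
        {
            "sparsity": levels,
            "group1_value": va,
            "group2_value": vb,
            "diff": va - vb,
        }
    )


def permutation_test(
    thickness_a: ThicknessMatrix,
    thickness_b: ThicknessMatrix,
    covariates: CovariateTable,
    grid: SparsityGrid,
    metric: Metric | str,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "greater",
    pmap: ParcellationMap | None = None,
    ranking: str = "signed",
) -> PermutationResult:
    """Label-permutation test of the group difference at every sparsity.

    Each permutation reassigns subjects to groups of the original sizes
    and recomputes residualization, partial correlation, binarization and
    the metric from scratch.  ``tail='greater'`` tests whether group 1
    exceeds group 2 (observed diff against the upper 95% point of the
    null); ``tail='less'`` the reverse.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if isinstance(metric, str):
        metric = make_metric(metric, pmap)
    if thickness_a.n_subjects < 4 or thickness_b.n_subjects < 4:
        raise NetworkConstructionError("each group needs at least 4 subjects")

    values, design, n_a, n_b = _pool(thickness_a, thickness_b, covariates)
    n_total = n_a + n_b
    n_regions = values.shape[1]
    levels = grid.levels()
    edge_counts = np.array([target_edges(s, n_regions) for s in levels])
    iu, ju = np.triu_indices(n_regions, k=1)

    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_total)
    va, vb = _curves_for_split(
        values, design, idx_a, idx_b, edge_counts, metric, iu, ju, ranking
    )
    observed = va - vb

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, levels.size))
    for p in range(n_perm):
        perm = rng.permutation(n_total)
        pa, pb = perm[:n_a], perm[n_a:]
        na_v, nb_v = _curves_for_split(
            values, design, pa, pb, edge_counts, metric, iu, ju, ranking
        )
        null[p] = na_v - nb_v

    null_mean = np.nanmean(null, axis=0)
    n_valid = np.sum(~np.isnan(null), axis=0)
    with np.errstate(invalid="ignore"):
        if tail == "greater":
            crit = np.nanpercentile(null, 95, axis=0)
            exceed = np.nansum(null >= observed[None, :], axis=0)
            significant = observed > crit
        else:
            crit = np.nanpercentile(null, 5, axis=0)
            exceed = np.nansum(null <= observed[None, :], axis=0)
            significant = observed < crit
    p_values = (1.0 + exceed) / (n_valid + 1.0)
    p_values = np.where(np.isnan(observed), np.nan, p_values)
    significant = np.where(np.isnan(observed), False, significant)

    table = pd.DataFrame(
        {
            "sparsity": levels,
            "group1_value": va,
            "group2_value": vb,
            "diff": observed,
            "null_mean": null_mean,
            "crit95": crit,
            "p": p_values,
            "significant": significant.astype(bool),
        }
    )
    return PermutationResult(
        table=table,
        metric=metric.name,
        n_permutations=n_perm,
        seed=seed,
        tail=tail,
        null_diffs=null,
    )
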