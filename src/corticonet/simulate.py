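"""Synthetic two-group cortical-thickness cohorts and toy graph fixtures.

No subject-level MRI data accompany the study design this pipeline
targets, so every stage is exercised on simulated cohorts with known
ground truth.  The generator draws regional thickness from a latent
factor model aligned to the functional subsystems:

    x_ij = mu_j + beta_age * age_i + beta_sex * sex_i
           + sd * (lambda * f_{i, s(j)} + eps_ij)

where ``f_{i,s}`` is subject i's score on the factor of subsystem s and
the five factors are jointly Gaussian with correlation matrix Phi.  With
``lambda = sqrt(within_r)`` and ``sd(eps) = sqrt(1 - within_r)``, the
population correlation is ``within_r`` between same-subsystem regions
and ``within_r * Phi_st`` between regions of subsystems s and t — i.e.
``between_r`` under the default Phi_st = between_r / within_r.  A group
effect is planted by multiplying selected inter-subsystem factor
correlations in group B, which lowers exactly the cross-system coupling
the inter-network efficiency analysis measures, leaving everything else
untouched.

Defaults emulate the two-group design the pipeline is meant for: 81 vs
38 subjects, regional means 2–4 mm, ages uniform on 25–40 years, sex
balanced, small linear age/sex effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import BinaryNetwork, CovariateTable, ThicknessMatrix
from .parcellation import ParcellationMap

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "toy_graph"]


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for a two-group synthetic cohort.

    within_r / between_r are *region-level* population correlations
    (same-subsystem and cross-subsystem respectively); pair_between_r
    overrides between_r for named subsystem pairs; group_b_coupling
    multiplies the cross-subsystem factor correlation for named pairs in
    group B only (e.g. {("strategic_executive", "language"): 0.5} plants
    a 50% coupling deficit).
    """

    n_a: int = 81
    n_b: int = 38
    mean_range: tuple[float, float] = (2.0, 4.0)
    sd: float = 0.2  # total non-covariate SD per region, mm
    within_r: float = 0.5
    between_r: float = 0.15
    pair_between_r: Mapping[tuple[str, str], float] = field(default_factory=dict)
    group_b_coupling: Mapping[tuple[str, str], float] = field(default_factory=dict)
    beta_age: float = -0.01  # mm per year
    beta_sex: float = 0.05  # mm, level 1 minus level 0
    age_range: tuple[float, float] = (25.0, 40.0)
    thickness_floor: float = 0.5  # mm; clip guard, must stay essentially inactive


@dataclass
class SyntheticCohort:
    thickness_a: ThicknessMatrix
    thickness_b: ThicknessMatrix
    covariates: CovariateTable
    ground_truth: dict


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _factor_correlation(
    systems: list[str], config: CohortConfig, group_b: bool
) -> np.ndarray:
    """Phi: correlation matrix of the subsystem factors."""
    if not 0 < config.within_r < 1:
        raise SimulationConfigError("within_r must be in (0, 1)")
    k = len(systems)
    phi = np.eye(k)
    overrides = {_canonical_pair(*p): v for p, v in config.pair_between_r.items()}
    deficits = {_canonical_pair(*p): v for p, v in config.group_b_coupling.items()}
    for i in range(k):
        for j in range(i + 1, k):
            pair = _canonical_pair(systems[i], systems[j])
            between = overrides.get(pair, config.between_r)
            coupling = between / config.within_r
            if group_b:
                coupling *= deficits.get(pair, 1.0)
            if not -1 < coupling < 1:
                raise SimulationConfigError(
                    f"implied factor correlation {coupling:.3f} for {pair} "
                    "is outside (-1, 1); lower between_r or raise within_r"
                )
            phi[i, j] = phi[j, i] = coupling
    eig = np.linalg.eigvalsh(phi)
    if eig.min() <= 1e-10:
        raise SimulationConfigError(
            f"factor correlation matrix is not positive definite "
            f"(min eigenvalue {eig.min():.2e}); couplings are inconsistent"
        )
    return phi


def _draw_group(
    rng: np.random.Generator,
    n: int,
    mu: np.ndarray,
    system_of: np.ndarray,
    phi: np.ndarray,
    config: CohortConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = mu.size
    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    lam = np.sqrt(config.within_r)
    eps_sd = np.sqrt(1.0 - config.within_r)
    chol = np.linalg.cholesky(phi)
    factors = rng.standard_normal((n, phi.shape[0])) @ chol.T
    noise = rng.standard_normal((n, p)) * eps_sd
    latent = lam * factors[:, system_of] + noise
    x = (
        mu[None, :]
        + config.beta_age * age[:, None]
        + config.beta_sex * sex[:, None]
        + config.sd * latent
    )
    return x, age, sex


def generate_cohort(
    pmap: ParcellationMap, config: CohortConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """Draw a reproducible two-group cohort with known generating process.

    Group A is always drawn from the baseline coupling structure; group B
    shares it except for the configured ``group_b_coupling`` multipliers,
    so with an empty mapping the two groups are exchangeable (a null
    cohort).
    """
    config = config or CohortConfig()
    if config.sd <= 0:
        raise SimulationConfigError("sd must be positive")
    if config.n_a < 2 or config.n_b < 2:
        raise SimulationConfigError("each group needs at least 2 subjects")
    systems = pmap.subsystems
    sys_index = {s: k for k, s in enumerate(systems)}
    system_of = np.array([sys_index[r.subsystem] for r in pmap.regions])
    phi_a = _factor_correlation(systems, config, group_b=False)
    phi_b = _factor_correlation(systems, config, group_b=True)

    rng = np.random.default_rng(seed)
    mu = rng.uniform(*config.mean_range, size=pmap.n_regions)
    xa, age_a, sex_a = _draw_group(rng, config.n_a, mu, system_of, phi_a, config)
    xb, age_b, sex_b = _draw_group(rng, config.n_b, mu, system_of, phi_b, config)

    clipped = int((xa < config.thickness_floor).sum() + (xb < config.thickness_floor).sum())
    total = xa.size + xb.size
    if clipped / total >= 1e-3:
        raise SimulationConfigError(
            f"{clipped}/{total} values fell below the {config.thickness_floor} mm "
            "floor; the configured means/SD are not thickness-like"
        )
    xa = np.maximum(xa, config.thickness_floor)
    xb = np.maximum(xb, config.thickness_floor)

    labels = pmap.labels
    ids_a = [f"A{i:03d}" for i in range(config.n_a)]
    ids_b = [f"B{i:03d}" for i in range(config.n_b)]
    thickness_a = ThicknessMatrix(xa, ids_a, labels)
    thickness_b = ThicknessMatrix(xb, ids_b, labels)
    covariates = CovariateTable(
        ids_a + ids_b,
        np.concatenate([age_a, age_b]),
        np.concatenate([sex_a, sex_b]),
    )
    ground_truth = {
        "seed": seed,
        "region_means_mm": mu.tolist(),
        "subsystem_of_region": [systems[k] for k in system_of],
        "within_r": config.within_r,
        "between_r": config.between_r,
        "pair_between_r": {"|".join(k): v for k, v in config.pair_between_r.items()},
        "group_b_coupling": {"|".join(k): v for k, v in config.group_b_coupling.items()},
        "beta_age": config.beta_age,
        "beta_sex": config.beta_sex,
        "factor_correlation_a": phi_a.tolist(),
        "factor_correlation_b": phi_b.tolist(),
        "n_clipped": clipped,
    }
    return SyntheticCohort(thickness_a, thickness_b, covariates, ground_truth)


# ---------------------------------------------------------------------------
# deterministic toy graphs for metric oracles


def _from_edges(n: int, edges: list[tuple[int, int]]) -> BinaryNetwork:
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    sparsity = 2 * len(edges) / (n * (n - 1)) if n > 1 else 1.0
    return BinaryNetwork(adj, sparsity=max(sparsity, 1e-12))


def toy_graph(name: str, n: int = 5, k: int = 3, seed: int = 0) -> BinaryNetwork:
    """Named deterministic fixtures used throughout the test oracles.

    - ``path3``: a–b–c chain.
    - ``star_k``: hub with ``k`` leaves.
    - ``triangle``: K3.
    - ``two_triangles_bridge``: two triangles joined by one bridge edge
      (6 nodes, 7 edges) — the classic two-module fixture.
    - ``complete_n``: K_n (``n`` nodes).
    - ``planted_2block``: two blocks of n//2 nodes, within-block edge
      probability 0.9, between 0.05, drawn with ``seed``.
    """
    if name == "path3":
        return _from_edges(3, [(0, 1), (1, 2)])
    if name == "star_k":
        return _from_edges(k + 1, [(0, i) for i in range(1, k + 1)])
    if name == "triangle":
        return _from_edges(3, [(0, 1), (1, 2), (0, 2)])
    if name == "two_triangles_bridge":
        return _from_edges(
            6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        )
    if name == "complete_n":
        return _from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])
    if name == "planted_2block":
        rng = np.random.default_rng(seed)
        half = n // 2
        adj = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < half) == (j < half)
                if rng.random() < (0.9 if same else 0.05):
                    adj[i, j] = adj[j, i] = 1
        return BinaryNetwork(adj, sparsity=max(adj.sum() / (n * (n - 1)), 1e-12))
    raise KeyError(f"unknown toy graph {name!r}")
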