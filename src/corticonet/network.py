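"""Group-level covariance network construction.

A structural covariance network treats the correlation, across subjects,
of regional cortical thickness as an edge weight between regions.  The
construction here follows the standard recipe for group comparisons:

1. residualize each region's thickness against intercept + age + sex
   (ordinary least squares), so nuisance covariates cannot drive
   inter-regional correlation;
2. correlate residual columns pairwise (a partial correlation given the
   covariates);
3. threshold the correlation matrix to a *fixed sparsity* ``S`` — keep
   exactly ``round(S * N(N-1)/2)`` strongest edges — so networks compared
   across groups always have the same edge count.

Edge ranking is by signed correlation by default (positive covariance
read as connectivity); ``ranking="absolute"`` ranks by magnitude.  Ties
at the cutoff are broken by correlation descending, then lexicographic
(i, j) ascending, which makes the retained edge set reproducible
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ThicknessMatrix",
    "CovariateTable",
    "CorrelationMatrix",
    "BinaryNetwork",
    "NetworkConstructionError",
    "residualize_thickness",
    "partial_correlation_matrix",
    "target_edges",
    "binarize_at_sparsity",
    "read_thickness_csv",
    "read_covariates_csv",
    "write_edge_list",
]

RANKINGS = ("signed", "absolute")


class NetworkConstructionError(ValueError):
    pass


@dataclass
class ThicknessMatrix:
    """Subjects × regions mean cortical thickness (mm)."""

    values: np.ndarray
    subject_ids: list[str]
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise NetworkConstructionError("thickness values must be 2-D")
        n, p = self.values.shape
        if len(self.subject_ids) != n or len(self.region_labels) != p:
            raise NetworkConstructionError("thickness labels do not match shape")
        if not np.all(np.isfinite(self.values)):
            raise NetworkConstructionError("thickness contains missing/non-finite values")
        if np.any(self.values <= 0):
            raise NetworkConstructionError("thickness values must be positive (mm)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.region_labels,
        )


@dataclass
class CovariateTable:
    """Per-subject nuisance covariates: age (years) and sex (binary)."""

    subject_ids: list[str]
    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        sex = np.asarray(self.sex)
        levels = np.unique(sex)
        if levels.size > 2:
            raise NetworkConstructionError(
                f"sex must be two-level; found levels {levels.tolist()}"
            )
        # accept any two-level coding, recode to 0/1 in sorted-level order
        self.sex = np.searchsorted(levels, sex).astype(float)
        if len(self.subject_ids) != self.age.size or self.age.size != self.sex.size:
            raise NetworkConstructionError("covariate columns do not align")
        if np.any(self.age <= 0) or not np.all(np.isfinite(self.age)):
            raise NetworkConstructionError("age must be positive and finite")

    def subset(self, subject_ids: list[str]) -> "CovariateTable":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            idx = [pos[s] for s in subject_ids]
        except KeyError as e:
            raise NetworkConstructionError(f"covariates missing subject {e.args[0]!r}")
        return CovariateTable(list(subject_ids), self.age[idx], self.sex[idx])

    def design_matrix(self) -> np.ndarray:
        """Intercept + age + sex columns."""
        return np.column_stack([np.ones(self.age.size), self.age, self.sex])


@dataclass
class CorrelationMatrix:
    """Region × region partial correlations with the sample size used."""

    values: np.ndarray
    n_subjects: int
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise NetworkConstructionError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise NetworkConstructionError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise NetworkConstructionError("correlation diagonal must be 1")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if np.any(np.abs(off) > 1 + 1e-12):
            raise NetworkConstructionError("off-diagonal correlations outside [-1, 1]")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency at a stated sparsity."""

    adjacency: np.ndarray
    sparsity: float
    region_labels: list[str] | None = None
    edge_count: int = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkConstructionError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise NetworkConstructionError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise NetworkConstructionError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise NetworkConstructionError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)
        self.edge_count = int(a.sum()) // 2

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu, ju] == 1
        return list(zip(iu[keep].tolist(), ju[keep].tolist()))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g


def _align(thickness: ThicknessMatrix, covariates: CovariateTable) -> CovariateTable:
    return covariates.subset(thickness.subject_ids)


def residualize_thickness(
    thickness: ThicknessMatrix, covariates: CovariateTable
) -> np.ndarray:
    """OLS residuals of each region column against intercept + age + sex.

    Returns a subjects × regions array of residuals (zero column means).
    Constant covariate columns degrade gracefully to the intercept-only
    projection; a design with no variation at all beyond what the
    intercept spans (and fewer effective regressors than needed) is fine,
    but a rank check guards against pathological duplicate columns.
    """
    cov = _align(thickness, covariates)
    x = cov.design_matrix()
    # drop covariate columns that are constant (absorbed by the intercept)
    keep = [0] + [j for j in (1, 2) if np.ptp(x[:, j]) > 0]
    x = x[:, keep]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise NetworkConstructionError(
            "degenerate covariate design (collinear age/sex columns)"
        )
    y = thickness.values
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_correlation_matrix(
    thickness: ThicknessMatrix, covariates: CovariateTable
) -> CorrelationMatrix:
    """Partial correlations of regional thickness given age and sex.

    Entry (i, j) is the Pearson correlation of the age/sex-adjusted
    residual columns i and j.
    """
    cov = _align(thickness, covariates)
    n = thickness.n_subjects
    if n < cov.design_matrix().shape[1] + 2:
        raise NetworkConstructionError(
            f"need more subjects than covariates + 2; got n={n}"
        )
    resid = residualize_thickness(thickness, covariates)
    sd = resid.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [thickness.region_labels[i] for i in dead]
        raise NetworkConstructionError(
            f"zero residual variance, correlation undefined for region(s) {names}"
        )
    r = np.corrcoef(resid, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, n_subjects=n, region_labels=thickness.region_labels)


def target_edges(sparsity: float, n_regions: int) -> int:
    """Edge count at sparsity ``S``: round(S * N(N-1)/2), half away from zero."""
    if not 0 < sparsity <= 1:
        raise NetworkConstructionError(f"sparsity must be in (0, 1]; got {sparsity}")
    if n_regions < 2:
        raise NetworkConstructionError("need at least 2 regions")
    max_edges = n_regions * (n_regions - 1) // 2
    return int(math.floor(sparsity * max_edges + 0.5))


def ranked_pair_order(values: np.ndarray, ranking: str = "signed") -> np.ndarray:
    """Indices into the upper-triangle pair list, strongest edge first.

    Pairs are enumerated in lexicographic (i, j) order (numpy
    ``triu_indices``); a stable sort on descending strength therefore
    breaks exact ties toward the lexicographically smaller pair.
    """
    if ranking not in RANKINGS:
        raise NetworkConstructionError(f"unknown ranking {ranking!r}; use {RANKINGS}")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    if ranking == "absolute":
        w = np.abs(w)
    return np.argsort(-w, kind="stable")


def binarize_at_sparsity(
    corr: CorrelationMatrix, sparsity: float, ranking: str = "signed"
) -> BinaryNetwork:
    """Keep exactly ``target_edges(S, N)`` strongest region pairs as edges."""
    n = corr.n_regions
    m = target_edges(sparsity, n)
    iu, ju = np.triu_indices(n, k=1)
    w = corr.values[iu, ju]
    finite = np.isfinite(w)
    if m > int(finite.sum()):
        raise NetworkConstructionError(
            f"sparsity {sparsity} needs {m} edges but only {int(finite.sum())} "
            "finite correlations are available"
        )
    order = ranked_pair_order(corr.values, ranking)
    keep = order[:m]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, sparsity=sparsity, region_labels=corr.region_labels)


# ---------------------------------------------------------------------------
# I/O

def read_thickness_csv(
    path: str | Path, region_labels: list[str] | None = None
) -> ThicknessMatrix:
    """Read a thickness table: first column subject_id, one column per region.

    Comma- or tab-separated (inferred from the suffix).  When
    ``region_labels`` is given, columns are validated and reordered to it.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    if region_labels is not None:
        missing = [c for c in region_labels if c not in df.columns]
        if missing:
            raise NetworkConstructionError(
                f"{path}: thickness table missing region column(s) {missing[:5]}"
            )
        df = df[region_labels]
    return ThicknessMatrix(
        df.to_numpy(float), [str(s) for s in df.index], list(df.columns)
    )


def read_covariates_csv(path: str | Path) -> CovariateTable:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    need = {"subject_id", "age", "sex"}
    if not need.issubset(df.columns):
        raise NetworkConstructionError(
            f"{path}: covariates need columns {sorted(need)}"
        )
    return CovariateTable(
        [str(s) for s in df["subject_id"]],
        df["age"].to_numpy(float),
        df["sex"].to_numpy(),
    )


def write_edge_list(net: BinaryNetwork, path: str | Path) -> None:
    """TSV edge list with region labels (or indices when unlabeled)."""
    labels = net.region_labels or [str(i) for i in range(net.n_nodes)]
    with open(path, "w") as fh:
        fh.write("region_a\tregion_b\n")
        for i, j in net.edges():
            fh.write(f"{labels[i]}\t{labels[j]}\n")
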