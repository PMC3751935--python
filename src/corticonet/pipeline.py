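"""End-to-end analysis runs: configuration, outputs and manifest.

``run_full_analysis`` executes the whole pipeline on a two-group
thickness dataset: group correlation matrices, binarized networks across
the sparsity grid, whole-network metric curves, hub/module
characterization at the hub sparsity, and permutation tests for the
whole-network metrics and the three executive inter-system pairs.  All
defaults reproduce the canonical analysis settings (grid 0.07–0.40 step
0.01, hub sparsity 0.23, 1000 permutations).

Networks binarized for the observed curves are built once per group and
reused by the hub analysis, so every reported observed value comes from
the same matrices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import compute_node_metrics, modularity_partition
from .network import (
    binarize_at_sparsity,
    partial_correlation_matrix,
    read_covariates_csv,
    read_thickness_csv,
    write_edge_list,
)
from .parcellation import default_parcellation, load_parcellation
from .permutation import SparsityGrid, make_metric, permutation_test
from .subsystems import (
    DEFAULT_P_THRESHOLD,
    DEFAULT_Z_THRESHOLD,
    classify_connector_nodes,
    identify_hubs,
)

__all__ = ["RunConfig", "run_full_analysis", "PipelineError"]

#: Inter-system pairs tested by default: executive control against the
#: three systems it exerts top-down control over.
DEFAULT_INTERNETWORK_PAIRS = (
    ("strategic_executive", "language"),
    ("strategic_executive", "mnemonic_emotional"),
    ("strategic_executive", "sensorimotor"),
)
DEFAULT_WHOLE_NETWORK_METRICS = ("E_glob", "E_loc", "beta")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    thickness_a: str
    thickness_b: str
    covariates: str
    output_dir: str
    parcellation: str | None = None  # None -> packaged default map
    s_min: float = 0.07
    s_max: float = 0.40
    s_step: float = 0.01
    hub_sparsity: float = 0.23
    n_perm: int = 1000
    seed: int = 0
    ranking: str = "signed"
    tail: dict = field(default_factory=dict)  # metric name -> greater/less
    p_threshold: float = DEFAULT_P_THRESHOLD
    z_threshold: float = DEFAULT_Z_THRESHOLD

    @property
    def grid(self) -> SparsityGrid:
        return SparsityGrid(self.s_min, self.s_max, self.s_step)

    def validate(self) -> None:
        grid = self.grid  # raises on bad bounds
        if self.hub_sparsity not in grid:
            raise ValueError(
                f"hub_sparsity {self.hub_sparsity} is not a level of the "
                f"sparsity grid [{self.s_min}, {self.s_max}] step {self.s_step}"
            )
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_full_analysis(config: RunConfig) -> dict:
    """Run the complete pipeline and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure raises :class:`PipelineError` naming the stage, after
    writing a manifest marked incomplete.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "status": "incomplete",
        "stages_completed": [],
    }

    def _fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(stage, str(exc)) from exc

    stage = "load_inputs"
    try:
        pmap = (
            load_parcellation(config.parcellation)
            if config.parcellation
            else default_parcellation()
        )
        thickness_a = read_thickness_csv(config.thickness_a, pmap.labels)
        thickness_b = read_thickness_csv(config.thickness_b, pmap.labels)
        covariates = read_covariates_csv(config.covariates)
    except Exception as e:  # noqa: BLE001 - stage boundary
        _fail(stage, e)
    manifest["stages_completed"].append(stage)

    grid = config.grid
    levels = grid.levels()
    results: dict = {"pmap": pmap}

    stage = "correlation_matrices"
    try:
        corr = {}
        for name, thick in (("group1", thickness_a), ("group2", thickness_b)):
            corr[name] = partial_correlation_matrix(thick, covariates)
            df = pd.DataFrame(corr[name].values, index=pmap.labels, columns=pmap.labels)
            df.to_csv(out / f"correlation_{name}.tsv", sep="\t", float_format="%.10g")
    except Exception as e:
        _fail(stage, e)
    manifest["stages_completed"].append(stage)

    stage = "binarize_networks"
    try:
        nets = {name: {} for name in corr}
        edge_dir = out / "edges"
        edge_dir.mkdir(exist_ok=True)
        for name, c in corr.items():
            for s in levels:
                net = binarize_at_sparsity(c, float(s), config.ranking)
                nets[name][float(s)] = net
                write_edge_list(net, edge_dir / f"{name}_S{s:.2f}.tsv")
    except Exception as e:
        _fail(stage, e)
    manifest["stages_completed"].append(stage)

    stage = "metric_curves"
    try:
        metric_fns = {m: make_metric(m, pmap) for m in DEFAULT_WHOLE_NETWORK_METRICS}
        rows = []
        for s in levels:
            for name in nets:
                adj = nets[name][float(s)].adjacency
                row = {"sparsity": float(s), "group": name}
                for m, fn in metric_fns.items():
                    row[m] = fn.evaluate(adj)
                rows.append(row)
        curves = pd.DataFrame(rows)
        _write_tsv(curves, out / "whole_network_curves.tsv")
        results["curves"] = curves
    except Exception as e:
        _fail(stage, e)
    manifest["stages_completed"].append(stage)

    stage = "hub_analysis"
    try:
        hub_tables = {}
        for name in nets:
            net = nets[name][config.hub_sparsity]
            partition = modularity_partition(net, seed=config.seed)
            m = compute_node_metrics(net, partition)
            m = identify_hubs(m)
            m = classify_connector_nodes(m, config.p_threshold, config.z_threshold)
            m.insert(1, "subsystem", [r.subsystem for r in pmap.regions])
            m["modularity_Q"] = partition.q
            _write_tsv(m, out / f"hub_table_{name}.tsv")
            hub_tables[name] = m
        results["hub_tables"] = hub_tables
    except Exception as e:
        _fail(stage, e)
    manifest["stages_completed"].append(stage)

    stage = "permutation_tests"
    try:
        metric_names = list(DEFAULT_WHOLE_NETWORK_METRICS) + [
            f"internetwork:{a}:{b}" for a, b in DEFAULT_INTERNETWORK_PAIRS
        ]
        perm_rows = []
        perm_results = {}
        for mname in metric_names:
            res = permutation_test(
                thickness_a,
                thickness_b,
                covariates,
                grid,
                mname,
                n_perm=config.n_perm,
                seed=config.seed,
                tail=config.tail.get(mname, "greater"),
                pmap=pmap,
                ranking=config.ranking,
            )
            t = res.table.copy()
            t.insert(1, "metric", mname)
            perm_rows.append(t)
            perm_results[mname] = res
        perm_table = pd.concat(perm_rows, ignore_index=True)
        _write_tsv(perm_table, out / "permutation_results.tsv")
        results["permutation"] = perm_results
    except Exception as e:
        _fail(stage, e)
    manifest["stages_completed"].append(stage)

    manifest["status"] = "complete"
    manifest["outputs"] = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
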