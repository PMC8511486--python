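"""End-to-end configured pipeline: volumes in, networks/stats/hubs out.

Stage order mirrors the analysis a covariance-network study reports:
residualize -> per-group correlation network -> density-threshold stack ->
global metric curves -> permutation group comparison -> betweenness hubs.
Every output is a text file (tidy CSV, labeled square CSV, or JSON); a
serialized copy of the configuration and a timestamped run log land in the
output directory. Given an identical configuration the result files are
byte-identical; the run log (wall-clock timestamps) is the documented
exception.

The master seed is expanded into per-stage streams through a fixed counter
scheme (``default_rng([seed, stage_counter])``), so any stage can be re-run
in isolation and reproduce its part of the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hubs import compare_hubs, detect_hubs
from .io import read_subject_table, write_labeled_matrix, write_subject_table
from .metrics import (
    GLOBAL_METRIC_NAMES,
    auc_over_densities,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    small_world_indices,
)
from .network import DensityGrid, build_stack, group_correlation
from .permutation import (
    PermutationResult,
    PermutationSpec,
    global_metric_difference_test,
    nodal_betweenness_test,
)
from .residualize import DEFAULT_COVARIATES, residualize
from .synthetic import CohortSpec, generate_cohort, write_ground_truth

__all__ = ["RunConfig", "run_pipeline"]

# stage counters for the documented seed-expansion scheme
_STAGE_SIMULATE = 0
_STAGE_OBSERVED_SW = 1


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one pipeline run.

    ``input_table`` is a CSV/TSV path; when None a synthetic cohort is
    generated from ``cohort`` (with the master seed).
    """

    out_dir: str = "results/run"
    input_table: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    density_min: float = 0.05
    density_max: float = 0.50
    density_step: float = 0.01
    edge_rank: str = "signed"
    n_perm: int = 1000
    n_random: int = 1000  # rewired ensemble for observed small-world indices
    n_random_in_permutation: int = 20
    perm_metrics: tuple[str, ...] = ("Cp", "Lp", "Eglob", "Eloc")
    run_nodal_test: bool = True
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.density_min < self.density_max <= 1):
            raise ValueError("require 0 < density_min < density_max <= 1")
        for m in self.perm_metrics:
            if m not in GLOBAL_METRIC_NAMES:
                raise ValueError(f"unknown metric {m!r} in perm_metrics")
        if self.input_table is None:
            self.cohort.validate()

    def grid(self) -> DensityGrid:
        n = int(round((self.density_max - self.density_min) / self.density_step)) + 1
        d = np.round(self.density_min + self.density_step * np.arange(n), 10)
        return DensityGrid(tuple(float(x) for x in d))

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["cohort"]["covariate_effects"] = dict(
            payload["cohort"]["covariate_effects"]
        )
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            c = raw["cohort"]
            for key in ("n_per_group", "within_r_by_group", "age_range", "education_range"):
                if key in c:
                    c[key] = tuple(c[key])
            raw["cohort"] = CohortSpec(**c)
        for key in ("covariates", "perm_metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _log(lines: list[str], msg: str) -> None:
    lines.append(f"{datetime.now(timezone.utc).isoformat()} {msg}")


def _observed_curves(
    resid, groups: dict[str, np.ndarray], grid: DensityGrid, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray]]:
    """Tidy global-metric curves, nodal AUC table and per-group nodal AUC
    vectors for the observed group labels."""
    rows = []
    nodal_rows = []
    nodal_auc: dict[str, np.ndarray] = {}
    for gname, members in groups.items():
        net = group_correlation(resid, members)
        stack = build_stack(net, grid, edge_rank=cfg.edge_rank)
        sw_rng = np.random.default_rng([cfg.seed, _STAGE_OBSERVED_SW])
        bc_curves = []
        for d, g in stack:
            a = g.adjacency
            _, cp = clustering_coefficient(a)
            try:
                lp = characteristic_path_length(a)
            except ValueError:
                lp = np.nan
            gamma, lam, sigma = small_world_indices(
                a, n_random=cfg.n_random, seed=sw_rng
            )
            vals = {
                "Cp": cp,
                "Lp": lp,
                "gamma": gamma,
                "lambda": lam,
                "sigma": sigma,
                "Eglob": global_efficiency(a),
                "Eloc": local_efficiency(a)[1],
            }
            for m, v in vals.items():
                rows.append({"group": gname, "density": d, "metric": m, "value": v})
            bc_curves.append(betweenness(g).betweenness_norm)
        bc = np.stack(bc_curves)
        auc = np.array(
            [auc_over_densities(bc[:, j], grid) for j in range(bc.shape[1])]
        )
        nodal_auc[gname] = auc
        for lab, v in zip(resid.region_labels, auc):
            nodal_rows.append(
                {"group": gname, "region": lab, "betweenness_auc": v}
            )
    return pd.DataFrame(rows), pd.DataFrame(nodal_rows), nodal_auc


def _perm_result_frame(res: PermutationResult, index_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            index_name: list(res.index),
            "observed": res.observed,
            "p_raw": res.p_raw,
            "p_fdr": res.p_fdr,
            "null_ci_low": res.null_ci_low,
            "null_ci_high": res.null_ci_high,
            "flagged": res.flags,
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle to ``out_dir``.

    Returns a summary dict (also written as ``summary.json``). Any stage
    failure raises a stage-named RuntimeError after writing an INCOMPLETE
    marker into the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list[str] = []
    _log(log, f"scnet {__version__} python {sys.version.split()[0]} seed {config.seed}")
    (out / "INCOMPLETE").write_text("run in progress or failed\n")

    stage = "load"
    try:
        if config.input_table is None:
            stage = "simulate"
            spec = dataclasses.replace(config.cohort, seed=config.seed)
            table, truth = generate_cohort(spec)
            write_subject_table(table, out / "cohort.csv")
            write_ground_truth(truth, out / "ground_truth.json")
            _log(log, f"simulated cohort: {len(table)} subjects, "
                       f"{len(truth.region_labels)} regions")
        else:
            table = read_subject_table(config.input_table)
            _log(log, f"loaded {config.input_table}: {len(table)} subjects")

        stage = "residualize"
        resid = residualize(table, covariates=config.covariates)
        resid.to_frame().to_csv(out / "residuals.csv")

        group_names = list(dict.fromkeys(table["group"]))
        if len(group_names) != 2:
            raise ValueError(f"need exactly 2 groups, found {group_names}")
        groups = {
            g: resid.rows_for(table.loc[table["group"] == g, "subject_id"])
            for g in group_names
        }
        grid = config.grid()

        stage = "network_construction"
        for gname, members in groups.items():
            net = group_correlation(resid, members)
            write_labeled_matrix(net.r, net.region_labels, out / f"correlation_{gname}.csv")
        _log(log, f"built correlation networks for {group_names}; "
                   f"grid of {len(grid)} densities")

        stage = "metric_curves"
        curves, nodal_table, nodal_auc = _observed_curves(resid, groups, grid, config)
        curves.to_csv(out / "global_curves.csv", index=False)
        nodal_table.to_csv(out / "nodal_betweenness.csv", index=False)
        _log(log, "computed global metric curves and nodal betweenness AUC")

        stage = "permutation_tests"
        pspec = PermutationSpec(
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.seed,
            n_random_small_world=config.n_random_in_permutation,
            edge_rank=config.edge_rank,
        )
        ga, gb = group_names
        markers = []
        for metric in config.perm_metrics:
            res = global_metric_difference_test(
                resid, groups[ga], groups[gb], grid, metric, pspec
            )
            _perm_result_frame(res, "density").to_csv(
                out / f"perm_global_{metric}.csv", index=False
            )
            for d, p_raw, p_fdr in zip(res.index, res.p_raw, res.p_fdr):
                markers.append(
                    {
                        "metric": metric,
                        "density": d,
                        "significant_uncorrected": bool(p_raw < config.alpha),
                        "significant_fdr": bool(p_fdr < config.alpha),
                    }
                )
            _log(log, f"permutation test done: {metric}")
        pd.DataFrame(markers).to_csv(out / "significance_markers.csv", index=False)

        nodal_sig = None
        if config.run_nodal_test:
            res = nodal_betweenness_test(resid, groups[ga], groups[gb], grid, pspec)
            _perm_result_frame(res, "region").to_csv(
                out / "perm_nodal_betweenness.csv", index=False
            )
            nodal_sig = {
                "uncorrected": [
                    r for r, p in zip(res.index, res.p_raw) if p < config.alpha
                ],
                "fdr": [r for r, p in zip(res.index, res.p_fdr) if p < config.alpha],
            }
            _log(log, "nodal betweenness permutation test done")

        stage = "hubs"
        reports = {
            g: detect_hubs(resid.region_labels, nodal_auc[g], group_name=g)
            for g in group_names
        }
        for g, rep in reports.items():
            (out / f"hubs_{g}.json").write_text(
                json.dumps(rep.as_dict(), indent=1, sort_keys=True)
            )
        common, only_a, only_b = compare_hubs(reports[ga], reports[gb])
        hub_cmp = pd.DataFrame(
            [
                {"category": "common", "region": r} for r in sorted(common)
            ]
            + [{"category": f"only_{ga}", "region": r} for r in sorted(only_a)]
            + [{"category": f"only_{gb}", "region": r} for r in sorted(only_b)]
        )
        hub_cmp.to_csv(out / "hubs_comparison.csv", index=False)
        _log(log, f"hubs: {ga}={len(reports[ga].hub_regions)}, "
                   f"{gb}={len(reports[gb].hub_regions)}, common={len(common)}")

        summary = {
            "groups": {g: int(len(m)) for g, m in groups.items()},
            "n_regions": len(resid.region_labels),
            "densities": [float(d) for d in grid],
            "perm_metrics": list(config.perm_metrics),
            "hub_counts": {g: len(r.hub_regions) for g, r in reports.items()},
            "common_hubs": sorted(common),
            "nodal_significant": nodal_sig,
            "seed": config.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (out / "INCOMPLETE").unlink()
        _log(log, "run complete")
        return summary
    except Exception as exc:
        _log(log, f"FAILED at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        (out / "run.log").write_text("\n".join(log) + "\n")
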