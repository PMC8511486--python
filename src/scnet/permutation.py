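"""Permutation inference for group differences in network topology.

Group-level covariance networks yield one network per group, not one per
subject, so parametric tests do not apply. Inference follows the standard
subject-relabeling scheme: the pooled, covariate-corrected volumes are
randomly reassigned to two pseudo-groups of the original sizes; both group
networks are rebuilt at every density; and the between-group difference in
each topology measure forms the permutation null distribution. Observed
differences are referred to that null.

p-values use the add-one convention p = (1 + #{|null| >= |obs|}) / (n_perm
+ 1), which is a valid permutation p-value and can never be exactly zero.
Benjamini–Hochberg FDR is applied across densities (global curves, per
metric) or across nodes (betweenness AUC test). Raw and FDR-adjusted
p-values are always reported side by side, as are the empirical null
confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

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
from .residualize import ResidualMatrix

__all__ = [
    "PermutationSpec",
    "PermutationResult",
    "permute_groups",
    "global_metric_difference_test",
    "nodal_betweenness_test",
    "fdr_bh",
]

Sidedness = Literal["two_sided", "greater", "less"]


@dataclass(frozen=True)
class PermutationSpec:
    """Settings for the subject-relabeling permutation tests.

    ``n_random_small_world`` caps the rewired-ensemble size used for
    gamma/lambda/sigma *inside* permutations; the full default of 1000
    random networks per graph is reserved for observed networks because the
    permutation loop multiplies it by n_perm x densities.
    """

    n_perm: int = 1000
    alpha: float = 0.05
    sidedness: Sidedness = "two_sided"
    seed: int = 0
    n_random_small_world: int = 20
    edge_rank: str = "signed"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.sidedness not in ("two_sided", "greater", "less"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistics, permutation null, p-values and null band.

    ``index`` labels the statistic axis: densities for global-metric
    curves, region labels for nodal tests. ``flags`` marks entries where
    the metric was undefined in at least one permutation (e.g. path length
    on a graph with no connected pairs) — such entries are reported, never
    silently dropped.
    """

    statistic_name: str
    index: tuple
    observed: np.ndarray
    null_samples: np.ndarray  # n_perm x len(index)
    p_raw: np.ndarray
    p_fdr: np.ndarray
    null_ci_low: np.ndarray
    null_ci_high: np.ndarray
    alpha: float
    flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def permute_groups(
    n_subjects: int, group_sizes: tuple[int, int], seed: int, index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random partition of ``range(n_subjects)`` into two groups
    of the original sizes; reproducible from (seed, index)."""
    na, nb = group_sizes
    if na + nb != n_subjects:
        raise ValueError(f"group sizes {group_sizes} do not sum to {n_subjects}")
    rng = np.random.default_rng([seed, index])
    perm = rng.permutation(n_subjects)
    return np.sort(perm[:na]), np.sort(perm[na:])


def _metric_fn(
    metric_name: str, n_random: int, seed_stream: np.random.Generator | None
) -> Callable[[np.ndarray], float]:
    """Map a metric name to a callable on a dense adjacency matrix.

    Small-world indices consume ``seed_stream`` for their rewired
    ensembles; the other metrics are deterministic.
    """
    if metric_name == "Cp":
        return lambda a: clustering_coefficient(a)[1]
    if metric_name == "Lp":
        return lambda a: characteristic_path_length(a)
    if metric_name == "Eglob":
        return global_efficiency
    if metric_name == "Eloc":
        return lambda a: local_efficiency(a)[1]
    if metric_name in ("gamma", "lambda", "sigma"):
        pos = {"gamma": 0, "lambda": 1, "sigma": 2}[metric_name]

        def fn(a: np.ndarray) -> float:
            return small_world_indices(a, n_random=n_random, seed=seed_stream)[pos]

        return fn
    raise ValueError(
        f"unknown metric {metric_name!r}; expected one of {GLOBAL_METRIC_NAMES}"
    )


def _curve(
    residuals: ResidualMatrix,
    rows: np.ndarray,
    grid: DensityGrid,
    fn: Callable[[np.ndarray], float],
    edge_rank: str,
) -> np.ndarray:
    """Metric value at every grid density for one group's network; an
    undefined metric at a density becomes NaN (flagged by the caller)."""
    net = group_correlation(residuals, rows)
    stack = build_stack(net, grid, edge_rank=edge_rank)
    out = np.empty(len(grid))
    for k, (_, g) in enumerate(stack):
        try:
            out[k] = fn(g.adjacency)
        except ValueError:
            out[k] = np.nan
    return out


def _pvalues(
    observed: np.ndarray, null: np.ndarray, sidedness: Sidedness
) -> np.ndarray:
    n_perm = null.shape[0]
    if sidedness == "two_sided":
        exceed = np.abs(null) >= np.abs(observed)[None, :]
    elif sidedness == "greater":
        exceed = null >= observed[None, :]
    else:
        exceed = null <= observed[None, :]
    return (1.0 + np.nansum(exceed, axis=0)) / (n_perm + 1.0)


def _assemble(
    name: str,
    index: tuple,
    observed: np.ndarray,
    null: np.ndarray,
    spec: PermutationSpec,
) -> PermutationResult:
    flags = np.isnan(observed) | np.isnan(null).any(axis=0)
    p_raw = _pvalues(observed, null, spec.sidedness)
    ok = ~np.isnan(p_raw)
    p_fdr = np.full_like(p_raw, np.nan)
    if ok.any():
        p_fdr[ok] = fdr_bh(p_raw[ok])
    lo = np.nanquantile(null, spec.alpha / 2, axis=0)
    hi = np.nanquantile(null, 1 - spec.alpha / 2, axis=0)
    return PermutationResult(
        statistic_name=name,
        index=index,
        observed=observed,
        null_samples=null,
        p_raw=p_raw,
        p_fdr=p_fdr,
        null_ci_low=lo,
        null_ci_high=hi,
        alpha=spec.alpha,
        flags=flags,
    )


def global_metric_difference_test(
    residuals: ResidualMatrix,
    group_a_rows: np.ndarray | Sequence[str],
    group_b_rows: np.ndarray | Sequence[str],
    grid: DensityGrid,
    metric_name: str,
    spec: PermutationSpec = PermutationSpec(),
) -> PermutationResult:
    """Per-density permutation test of the A − B difference in one global
    metric, rebuilding both group networks in every permutation."""
    rows_a = _as_rows(residuals, group_a_rows)
    rows_b = _as_rows(residuals, group_b_rows)
    sizes = (rows_a.size, rows_b.size)
    n_total = sizes[0] + sizes[1]
    pooled = np.concatenate([rows_a, rows_b])

    stochastic = metric_name in ("gamma", "lambda", "sigma")
    obs_stream = np.random.default_rng([spec.seed, 1_000_000]) if stochastic else None
    fn = _metric_fn(metric_name, spec.n_random_small_world, obs_stream)
    observed = _curve(residuals, rows_a, grid, fn, spec.edge_rank) - _curve(
        residuals, rows_b, grid, fn, spec.edge_rank
    )

    null = np.empty((spec.n_perm, len(grid)))
    for k in range(spec.n_perm):
        ia, ib = permute_groups(n_total, sizes, spec.seed, k)
        stream = np.random.default_rng([spec.seed, 1_000_001 + k]) if stochastic else None
        fnk = _metric_fn(metric_name, spec.n_random_small_world, stream)
        null[k] = _curve(residuals, pooled[ia], grid, fnk, spec.edge_rank) - _curve(
            residuals, pooled[ib], grid, fnk, spec.edge_rank
        )
    return _assemble(metric_name, tuple(grid), observed, null, spec)


def _normalized_betweenness_auc(
    residuals: ResidualMatrix, rows: np.ndarray, grid: DensityGrid, edge_rank: str
) -> np.ndarray:
    """Per-region AUC over the grid of mean-normalized betweenness."""
    net = group_correlation(residuals, rows)
    stack = build_stack(net, grid, edge_rank=edge_rank)
    curves = np.stack([betweenness(g).betweenness_norm for _, g in stack])
    return np.array(
        [auc_over_densities(curves[:, j], grid) for j in range(curves.shape[1])]
    )


def nodal_betweenness_test(
    residuals: ResidualMatrix,
    group_a_rows: np.ndarray | Sequence[str],
    group_b_rows: np.ndarray | Sequence[str],
    grid: DensityGrid,
    spec: PermutationSpec = PermutationSpec(),
) -> PermutationResult:
    """Per-region permutation test on the AUC of normalized betweenness,
    with BH-FDR across regions."""
    rows_a = _as_rows(residuals, group_a_rows)
    rows_b = _as_rows(residuals, group_b_rows)
    sizes = (rows_a.size, rows_b.size)
    pooled = np.concatenate([rows_a, rows_b])

    observed = _normalized_betweenness_auc(
        residuals, rows_a, grid, spec.edge_rank
    ) - _normalized_betweenness_auc(residuals, rows_b, grid, spec.edge_rank)
    null = np.empty((spec.n_perm, len(residuals.region_labels)))
    for k in range(spec.n_perm):
        ia, ib = permute_groups(sizes[0] + sizes[1], sizes, spec.seed, k)
        null[k] = _normalized_betweenness_auc(
            residuals, pooled[ia], grid, spec.edge_rank
        ) - _normalized_betweenness_auc(residuals, pooled[ib], grid, spec.edge_rank)
    return _assemble(
        "betweenness_auc", tuple(residuals.region_labels), observed, null, spec
    )


def _as_rows(residuals: ResidualMatrix, members) -> np.ndarray:
    members = np.asarray(members)
    if members.dtype.kind in "iu":
        return members.astype(int)
    return residuals.rows_for(members)


def fdr_bh(p_values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
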