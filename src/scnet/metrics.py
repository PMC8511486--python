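"""Graph-topology measures for binarized covariance networks.

Global measures: clustering coefficient (Cp), characteristic path length
(Lp), global efficiency (Eglob), local efficiency (Eloc), and the
small-world indices gamma, lambda and sigma obtained by normalizing Cp and
Lp against an ensemble of degree-matched rewired random networks
(sigma = gamma / lambda; sigma > 1 marks small-world organization).
Regional measure: betweenness centrality, reported raw and normalized by
the network mean.

Thresholded covariance networks are routinely disconnected at low density,
so Lp averages shortest paths over *connected* pairs only, while Eglob
handles disconnection natively (1/inf = 0). A ``strict`` flag turns
disconnection into an error for callers that want the textbook definitions.

Everything here is plain numpy on dense adjacency matrices (the graphs are
small — tens to a few hundred nodes — and these functions sit inside
permutation loops); betweenness delegates to networkx's Brandes
implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import BinaryGraph, DensityGrid

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "MetricCurve",
    "hop_distance_matrix",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "betweenness",
    "rewire_matched_random",
    "small_world_indices",
    "global_metrics",
    "auc_over_densities",
    "GLOBAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eglob", "Eloc")


@dataclass(frozen=True)
class GlobalMetrics:
    Cp: float
    Lp: float
    Eglob: float
    Eloc: float
    gamma: float
    lam: float
    sigma: float
    n_random_used: int

    def as_dict(self) -> dict[str, float]:
        return {
            "Cp": self.Cp,
            "Lp": self.Lp,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "Eglob": self.Eglob,
            "Eloc": self.Eloc,
        }


@dataclass(frozen=True)
class NodalMetrics:
    """Raw and mean-normalized betweenness per region.

    ``degenerate`` is set when mean raw betweenness is zero (e.g. complete
    graphs), in which case the normalized values are defined as all-zero.
    """

    betweenness_raw: np.ndarray
    betweenness_norm: np.ndarray
    region_labels: tuple[str, ...]
    degenerate: bool = False


@dataclass(frozen=True)
class MetricCurve:
    metric_name: str
    densities: tuple[float, ...]
    values: np.ndarray

    @property
    def auc(self) -> float:
        return auc_over_densities(self.values, DensityGrid(self.densities))


def _adj(g: BinaryGraph | np.ndarray) -> np.ndarray:
    a = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    return a.astype(bool)


def hop_distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by breadth-first boolean
    matrix expansion; unreachable pairs are inf, the diagonal is 0."""
    a = np.asarray(adj).astype(bool)
    n = a.shape[0]
    af = a.astype(np.float32)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a] = 1.0
    reached = a | np.eye(n, dtype=bool)
    d = 1
    while True:
        nxt = (reached.astype(np.float32) @ af) > 0
        nxt |= reached
        new = nxt & ~reached
        if not new.any():
            break
        d += 1
        dist[new] = d
        reached = nxt
    return dist


def clustering_coefficient(g: BinaryGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node fraction of realized edges among each node's neighbors, and
    the unweighted mean over all nodes (degree < 2 nodes score 0)."""
    a = _adj(g).astype(float)
    k = a.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0  # diag(A^3)/2
    possible = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return c, float(c.mean())


def characteristic_path_length(
    g: BinaryGraph | np.ndarray, strict: bool = False
) -> float:
    """Mean shortest-path length over connected unordered node pairs.

    With ``strict=True`` any disconnected pair raises instead.
    """
    a = _adj(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    dist = hop_distance_matrix(a)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    if strict and not finite.all():
        raise ValueError("graph is disconnected and strict mode is on")
    if not finite.any():
        raise ValueError("no connected node pairs — path length undefined")
    return float(d[finite].mean())


def global_efficiency(g: BinaryGraph | np.ndarray) -> float:
    """Mean of inverse shortest-path lengths over unordered pairs
    (disconnected pairs contribute 0)."""
    a = _adj(g)
    n = a.shape[0]
    if n < 2:
        return 0.0
    dist = hop_distance_matrix(a)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(g: BinaryGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """Per node, the global efficiency of the subgraph induced on its
    neighbors (nodes with < 2 neighbors score 0); and the network mean."""
    a = _adj(g)
    n = a.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nb = np.nonzero(a[i])[0]
        if nb.size >= 2:
            eff[i] = global_efficiency(a[np.ix_(nb, nb)])
    return eff, float(eff.mean())


def betweenness(g: BinaryGraph) -> NodalMetrics:
    """Brandes betweenness (fractional geodesic credit, unordered pairs),
    normalized by the network mean for group comparison."""
    a = _adj(g)
    graph = nx.from_numpy_array(a)
    raw = np.array(
        [v for _, v in sorted(nx.betweenness_centrality(graph, normalized=False).items())]
    )
    mean = raw.mean()
    if mean == 0:
        warnings.warn("mean betweenness is zero; normalized values set to 0")
        return NodalMetrics(raw, np.zeros_like(raw), g.region_labels, degenerate=True)
    return NodalMetrics(raw, raw / mean, g.region_labels)


def _edge_array(a: np.ndarray) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(a, k=1))
    return np.column_stack([iu, ju])


def rewire_matched_random(
    g: BinaryGraph | np.ndarray,
    n_swap_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Degree-preserving randomization by Maslov–Sneppen double-edge swaps.

    Repeatedly picks two edges (a-b, c-d) and rewires to (a-d, c-b),
    rejecting proposals that create self-loops or duplicate edges, until
    ``n_swap_per_edge * n_edges`` swaps succeed (or an attempt cap is hit).
    The degree sequence — hence density — is preserved exactly. If the
    graph admits no valid swap the input is returned unchanged with a
    warning.
    """
    a = _adj(g).astype(np.int8)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = _edge_array(a)
    m = len(edges)
    if m < 2:
        warnings.warn("graph has fewer than 2 edges; returned unchanged")
        return a.copy()
    edge_set = {(int(u), int(v)) for u, v in edges}
    target = n_swap_per_edge * m
    max_attempts = 100 * target
    done = attempts = 0
    edges = [tuple(map(int, e)) for e in edges]
    # random draws are consumed in batches; the stream order (pairs of edge
    # indices, then orientation flips, per batch) is part of the contract
    while done < target and attempts < max_attempts:
        batch = min(2 * (target - done) + 16, max_attempts - attempts)
        idx = rng.integers(0, m, size=(batch, 2))
        flips = rng.integers(0, 2, size=batch)
        for (i, j), flip in zip(idx, flips):
            if done >= target:
                break
            attempts += 1
            if i == j:
                continue
            u, v = edges[i]
            x, y = edges[j]
            if flip:
                x, y = y, x
            # propose u-x, v-y
            if u == x or v == y or u == y or v == x:
                continue
            e1 = (min(u, x), max(u, x))
            e2 = (min(v, y), max(v, y))
            if e1 in edge_set or e2 in edge_set:
                continue
            edge_set.discard((min(u, v), max(u, v)))
            edge_set.discard((min(x, y), max(x, y)))
            edge_set.add(e1)
            edge_set.add(e2)
            edges[i] = e1
            edges[j] = e2
            done += 1
    if done == 0:
        warnings.warn("no valid double-edge swap found; returned unchanged")
        return a.copy()
    out = np.zeros_like(a)
    idx = np.array(sorted(edge_set))
    out[idx[:, 0], idx[:, 1]] = 1
    out |= out.T
    return out


def small_world_indices(
    g: BinaryGraph | np.ndarray,
    n_random: int = 1000,
    seed: int | np.random.Generator = 0,
    n_swap_per_edge: int = 10,
) -> tuple[float, float, float]:
    """gamma, lambda, sigma against a rewired random-network ensemble.

    gamma = Cp(g) / mean Cp(ensemble); lambda = Lp(g) / mean Lp(ensemble);
    sigma = gamma / lambda. The ensemble preserves the degree sequence of
    ``g`` exactly.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    a = _adj(g)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _, cp = clustering_coefficient(a)
    lp = characteristic_path_length(a)
    cps = np.empty(n_random)
    lps = np.empty(n_random)
    for k in range(n_random):
        r = rewire_matched_random(a, n_swap_per_edge=n_swap_per_edge, seed=rng)
        _, cps[k] = clustering_coefficient(r)
        lps[k] = characteristic_path_length(r)
    mean_cp, mean_lp = cps.mean(), lps.mean()
    if mean_cp == 0 or mean_lp == 0:
        raise ValueError("degenerate graph: random-ensemble mean Cp or Lp is zero")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return gamma, lam, gamma / lam


def global_metrics(
    g: BinaryGraph | np.ndarray,
    n_random: int = 1000,
    seed: int | np.random.Generator = 0,
) -> GlobalMetrics:
    """All global measures of one binary graph in a single record."""
    _, cp = clustering_coefficient(g)
    lp = characteristic_path_length(g)
    gamma, lam, sigma = small_world_indices(g, n_random=n_random, seed=seed)
    return GlobalMetrics(
        Cp=cp,
        Lp=lp,
        Eglob=global_efficiency(g),
        Eloc=local_efficiency(g)[1],
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        n_random_used=n_random,
    )


def auc_over_densities(values: np.ndarray, grid: DensityGrid) -> float:
    """Trapezoidal area of a metric curve over the density grid — the
    threshold-free summary used for nodal comparisons."""
    v = np.asarray(values, dtype=float)
    d = grid.as_array()
    if v.shape != d.shape:
        raise ValueError(f"curve length {v.shape} does not match grid {d.shape}")
    return float(np.trapezoid(v, d))
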