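"""Group covariance network construction and density thresholding.

The group network is the region-by-region Pearson correlation matrix of the
covariate-corrected volumes across a group's subjects. Because correlation
magnitudes are not comparable across groups or studies, the matrix is
binarized over a *density grid*: at density ``d`` exactly
``round(d * N(N-1)/2)`` edges are kept — the largest off-diagonal
correlations by signed value (keeping positive covariance interpretable; an
absolute-value mode is available). Edge sets are nested across the grid,
so increasing density only adds edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .residualize import ResidualMatrix

__all__ = [
    "CovarianceNetwork",
    "DensityGrid",
    "BinaryGraph",
    "DensityGraphStack",
    "group_correlation",
    "binarize_at_density",
    "build_stack",
    "edge_count_for_density",
]

EdgeRank = Literal["signed", "absolute"]


@dataclass(frozen=True)
class CovarianceNetwork:
    """Symmetric Pearson correlation matrix with region labels."""

    r: np.ndarray
    region_labels: tuple[str, ...]
    n_subjects: int

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass(frozen=True)
class DensityGrid:
    """Strictly increasing edge-density fractions in (0, 1].

    The default grid is 0.05–0.50 in steps of 0.01 (46 values), the
    standard sweep for binarized covariance networks.
    """

    densities: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(5, 51) / 100.0, 2))
    )

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if d.size == 0 or np.any(d <= 0) or np.any(d > 1):
            raise ValueError("densities must lie in (0, 1]")
        if np.any(np.diff(d) <= 0):
            raise ValueError("densities must be strictly increasing")

    def __iter__(self) -> Iterator[float]:
        return iter(self.densities)

    def __len__(self) -> int:
        return len(self.densities)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.densities, dtype=float)


@dataclass(frozen=True)
class BinaryGraph:
    """Binarized covariance network: symmetric hollow 0/1 adjacency."""

    adjacency: np.ndarray
    density_achieved: float
    region_labels: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class DensityGraphStack:
    """Binary graphs indexed by density, nested by construction."""

    graphs: dict[float, BinaryGraph]
    source: CovarianceNetwork

    def __iter__(self) -> Iterator[tuple[float, BinaryGraph]]:
        return iter(self.graphs.items())

    @property
    def densities(self) -> tuple[float, ...]:
        return tuple(self.graphs)


def group_correlation(
    residuals: ResidualMatrix, group_members: Sequence[str] | np.ndarray
) -> CovarianceNetwork:
    """Pearson correlation network of one group's corrected volumes.

    ``group_members`` is either a list of subject ids or an integer row
    index array into the residual matrix.
    """
    members = np.asarray(group_members)
    rows = (
        members.astype(int)
        if np.issubdtype(members.dtype, np.integer)
        else residuals.rows_for(members)
    )
    if rows.size < 3:
        raise ValueError("need at least 3 subjects to correlate")
    sub = residuals.values[rows]
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        bad = [residuals.region_labels[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant residual column(s), correlation undefined: {bad}")
    r = np.corrcoef(sub, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CovarianceNetwork(r=r, region_labels=residuals.region_labels, n_subjects=rows.size)


def edge_count_for_density(n_regions: int, density: float) -> int:
    """Target edge count: round-half-away-from-zero of d * N(N-1)/2."""
    m = n_regions * (n_regions - 1) // 2
    return int(np.floor(density * m + 0.5))


def _ranked_edges(net: CovarianceNetwork, edge_rank: EdgeRank) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) pairs ordered by decreasing correlation,
    ties broken by lexicographic (i, j)."""
    n = net.n_regions
    iu, ju = np.triu_indices(n, k=1)
    vals = net.r[iu, ju]
    if edge_rank == "absolute":
        vals = np.abs(vals)
    elif edge_rank != "signed":
        raise ValueError(f"edge_rank must be 'signed' or 'absolute', got {edge_rank!r}")
    # triu_indices emits pairs in lexicographic (i, j) order, so a stable
    # sort on -value breaks ties lexicographically
    order = np.argsort(-vals, kind="stable")
    return iu[order], ju[order]


def _graph_from_edges(
    net: CovarianceNetwork, iu: np.ndarray, ju: np.ndarray, n_edges: int
) -> BinaryGraph:
    n = net.n_regions
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:n_edges], ju[:n_edges]] = 1
    adj |= adj.T
    achieved = n_edges / (n * (n - 1) // 2)
    return BinaryGraph(adjacency=adj, density_achieved=achieved, region_labels=net.region_labels)


def binarize_at_density(
    net: CovarianceNetwork, density: float, edge_rank: EdgeRank = "signed"
) -> BinaryGraph:
    """Keep exactly the top ``round(d * N(N-1)/2)`` correlations as edges."""
    if not (0 < density <= 1):
        raise ValueError(f"density must lie in (0, 1], got {density}")
    n_edges = edge_count_for_density(net.n_regions, density)
    if n_edges == 0:
        raise ValueError(f"density {density} yields zero edges — degenerate graph")
    iu, ju = _ranked_edges(net, edge_rank)
    return _graph_from_edges(net, iu, ju, n_edges)


def build_stack(
    net: CovarianceNetwork, grid: DensityGrid, edge_rank: EdgeRank = "signed"
) -> DensityGraphStack:
    """Binarize across the whole grid; one shared ranking guarantees the
    nestedness invariant (edges at d are a subset of edges at d' > d)."""
    iu, ju = _ranked_edges(net, edge_rank)
    graphs: dict[float, BinaryGraph] = {}
    for d in grid:
        n_edges = edge_count_for_density(net.n_regions, d)
        if n_edges == 0:
            raise ValueError(f"density {d} yields zero edges — degenerate graph")
        graphs[d] = _graph_from_edges(net, iu, ju, n_edges)
    return DensityGraphStack(graphs=graphs, source=net)
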