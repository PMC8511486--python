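"""Hub identification and viewer-file export.

A *hub* is a region whose betweenness centrality is at least one sample
standard deviation above the network mean. The default basis is the AUC of
mean-normalized betweenness over the density grid (threshold-free); a
single-density basis is available. Hub sets of two groups are compared as
an exact set partition (common / group-specific), and nodal tables or hub
reports can be exported in the BrainNet Viewer .node/.edge text dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["HubReport", "detect_hubs", "compare_hubs", "export_brainnet", "read_edge_file"]

HUB_COLOR = 2.0
NONHUB_COLOR = 1.0


@dataclass(frozen=True)
class HubReport:
    group_name: str
    hub_regions: tuple[str, ...]
    region_labels: tuple[str, ...]
    betweenness_values: np.ndarray
    threshold: float
    basis: str
    degenerate: bool = False  # zero variance: no hubs identifiable

    def as_dict(self) -> dict:
        return {
            "group_name": self.group_name,
            "basis": self.basis,
            "threshold": self.threshold,
            "hub_regions": list(self.hub_regions),
            "degenerate": self.degenerate,
            "betweenness": dict(
                zip(self.region_labels, map(float, self.betweenness_values))
            ),
        }


def detect_hubs(
    region_labels,
    values: np.ndarray,
    basis: str = "auc_over_grid",
    group_name: str = "",
) -> HubReport:
    """Regions with value >= mean + 1 sample SD (ddof=1).

    Zero-variance inputs yield an empty, flagged hub set rather than an
    error: every region is then exactly at the mean and none stands out.
    """
    labels = tuple(region_labels)
    v = np.asarray(values, dtype=float)
    if len(labels) != v.size:
        raise ValueError("labels and values differ in length")
    if v.size < 2 or not np.all(np.isfinite(v)):
        raise ValueError("need >= 2 regions with finite values")
    sd = v.std(ddof=1)
    threshold = v.mean() + sd
    if sd == 0:
        return HubReport(group_name, (), labels, v, threshold, basis, degenerate=True)
    hubs = tuple(lab for lab, val in zip(labels, v) if val >= threshold)
    return HubReport(group_name, hubs, labels, v, threshold, basis)


def compare_hubs(a: HubReport, b: HubReport) -> tuple[set, set, set]:
    """(common, only in a, only in b) over the union of both hub sets."""
    if set(a.region_labels) != set(b.region_labels):
        raise ValueError("hub reports cover different region sets")
    ha, hb = set(a.hub_regions), set(b.hub_regions)
    return ha & hb, ha - hb, hb - ha


def export_brainnet(
    nodal: pd.DataFrame,
    coordinates: pd.DataFrame,
    node_path: str | Path,
    adjacency: np.ndarray | None = None,
    edge_path: str | Path | None = None,
) -> None:
    """Write BrainNet Viewer text files.

    ``nodal`` needs columns ``region``, ``size`` and optional boolean
    ``hub``; ``coordinates`` needs ``region``, ``x``, ``y``, ``z``. The
    .node format is six whitespace-separated columns (x y z color size
    label); the .edge format is the full symmetric matrix.
    """
    coords = coordinates.set_index("region")
    missing = [r for r in nodal["region"] if r not in coords.index]
    if missing:
        raise ValueError(f"missing coordinates for region(s): {missing}")
    lines = []
    hubs = nodal["hub"] if "hub" in nodal else pd.Series(False, index=nodal.index)
    for (_, row), is_hub in zip(nodal.iterrows(), hubs):
        x, y, z = coords.loc[row["region"], ["x", "y", "z"]]
        color = HUB_COLOR if bool(is_hub) else NONHUB_COLOR
        lines.append(
            f"{x:.6g}\t{y:.6g}\t{z:.6g}\t{color:g}\t{row['size']:.6g}\t{row['region']}"
        )
    Path(node_path).write_text("\n".join(lines) + "\n")
    if adjacency is not None:
        if edge_path is None:
            raise ValueError("edge_path required when adjacency is given")
        a = np.asarray(adjacency)
        if a.shape[0] != a.shape[1] or not np.array_equal(a, a.T):
            raise ValueError("adjacency must be a square symmetric matrix")
        np.savetxt(edge_path, a, fmt="%g", delimiter="\t")


def read_edge_file(path: str | Path) -> np.ndarray:
    """Parse a BrainNet .edge file back into a matrix (round-trip safe)."""
    return np.loadtxt(path, delimiter="\t", ndmin=2)
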