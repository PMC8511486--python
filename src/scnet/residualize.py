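"""Covariate removal from regional volumes by per-region OLS.

Structural covariance is computed on *corrected* volumes: for every region
independently, the volume is regressed on an intercept, the nuisance
covariates (age, sex, education) and each subject's mean overall GM volume,
and the residuals are kept. Residualization is performed once on the pooled
sample (both groups together); the subject-relabeling permutation scheme in
:mod:`scnet.permutation` requires a single shared residual matrix.

The mean overall GM volume covariate is computed as the unweighted mean of
the region columns for each subject — a proxy for total GM volume, which
would require voxel data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import META_COLUMNS

__all__ = ["ResidualMatrix", "residualize", "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = ("age", "sex", "education")

MEAN_VOLUME_COVARIATE = "mean_gm_volume"


@dataclass(frozen=True)
class ResidualMatrix:
    """Subjects-by-regions residual volumes with bookkeeping.

    ``values[i, j]`` is subject i's residual volume in region j after OLS
    removal of the covariates; every column has (numerically) zero mean and
    is orthogonal to every covariate column. Subject order matches the
    input table.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    region_labels: tuple[str, ...]
    covariates_used: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def rows_for(self, subject_ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given subjects, in the given order."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        return np.array([pos[s] for s in subject_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.region_labels)
        )


def _encode_covariate(col: pd.Series, name: str) -> np.ndarray:
    """Numeric covariates pass through; a two-level categorical becomes a
    0/1 indicator; multi-level categoricals are one-hot with the first
    (sorted) level dropped as reference."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None]
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"covariate {name!r} is constant; design would be rank-deficient")
    return np.column_stack(
        [(col.astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]]
    )


def residualize(
    table: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    include_mean_volume: bool = True,
) -> ResidualMatrix:
    """Regress every region's volume on the covariates; return residuals.

    Parameters
    ----------
    table : subject table with the standard metadata columns followed by
        one numeric column per region.
    covariates : covariate column names, fitted in this order after the
        intercept.
    include_mean_volume : append each subject's mean regional volume as a
        final covariate (the correction the covariance literature applies
        for global GM differences).

    Raises
    ------
    ValueError : rank-deficient design (the offending column is named) or
        fewer subjects than design parameters.
    """
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise ValueError(f"covariates not in table: {missing}")
    region_labels = tuple(c for c in table.columns if c not in META_COLUMNS)
    if not region_labels:
        raise ValueError("table has no region volume columns")
    y = table[list(region_labels)].to_numpy(dtype=float)

    design_cols: list[np.ndarray] = [np.ones((len(table), 1))]
    names: list[str] = ["intercept"]
    for c in covariates:
        block = _encode_covariate(table[c], c)
        design_cols.append(block)
        names.extend([c] * block.shape[1])
    used = list(covariates)
    if include_mean_volume:
        design_cols.append(y.mean(axis=1, keepdims=True))
        names.append(MEAN_VOLUME_COVARIATE)
        used.append(MEAN_VOLUME_COVARIATE)
    x = np.hstack(design_cols)

    if len(table) < x.shape[1] + 1:
        raise ValueError(
            f"need at least {x.shape[1] + 1} subjects for {x.shape[1]} "
            f"design parameters, got {len(table)}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name a culprit: a column that adds no rank beyond the others
        for j in range(1, x.shape[1]):
            sub = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(
                    f"design matrix is rank-deficient: column {names[j]!r} is "
                    "collinear with the remaining covariates"
                )
        raise ValueError("design matrix is rank-deficient")

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return ResidualMatrix(
        values=resid,
        subject_ids=tuple(table["subject_id"].astype(str)),
        region_labels=region_labels,
        covariates_used=tuple(used),
    )
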