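"""File dialects: subject tables, labeled matrices, tidy metric tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import META_COLUMNS

__all__ = [
    "read_subject_table",
    "write_subject_table",
    "write_labeled_matrix",
    "read_labeled_matrix",
    "region_columns",
]


def region_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject-by-region volume table.

    Delimiter is sniffed from the extension (.tsv/.tab -> tab, else comma).
    All validation problems are collected and reported together, with
    (row, column) coordinates for cell-level issues.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    problems: list[str] = []
    for col in META_COLUMNS:
        if col not in table.columns:
            problems.append(f"missing required column {col!r}")
    if "subject_id" in table.columns:
        dup = table["subject_id"][table["subject_id"].duplicated()]
        if not dup.empty:
            problems.append(f"duplicated subject_id(s): {sorted(set(dup))}")
    regions = region_columns(table)
    if not regions and not problems:
        problems.append("no region volume columns found")
    for col in regions:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna()
        for row in table.index[bad]:
            problems.append(
                f"non-numeric or missing volume at (row {row}, column {col!r})"
            )
        table[col] = numeric
    if problems:
        raise ValueError("invalid subject table:\n  " + "\n  ".join(problems))
    return table


def write_subject_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_csv(path, sep=sep, index=False)


def write_labeled_matrix(m: np.ndarray, labels, path: str | Path) -> None:
    """Square matrix as CSV with region labels on both axes."""
    pd.DataFrame(m, index=list(labels), columns=list(labels)).to_csv(path)


def read_labeled_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
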