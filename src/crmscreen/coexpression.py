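"""Marker-based cell classification and co-expression summaries.

Cells are split into marker-positive and marker-negative at a normalized
expression threshold (default 0.5; a cell is negative when its expression is
strictly lower than the threshold, so exactly-threshold cells are positive).
Candidate transcripts are then summarized by how their expressing cells
overlap the marker-positive population.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "validate_expression_matrix",
    "classify_cells",
    "coexpression_summary",
    "read_expression_tsv",
]


def validate_expression_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    """Cells x genes matrix: unique ids, finite non-negative values."""
    if mat.index.has_duplicates:
        raise ValueError("duplicate cell ids")
    if mat.columns.has_duplicates:
        raise ValueError("duplicate gene ids")
    vals = mat.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression values must be finite")
    if (vals < 0).any():
        raise ValueError("expression values must be >= 0")
    return mat


def classify_cells(
    mat: pd.DataFrame, marker_gene: str, threshold: float = 0.5
) -> pd.Series:
    """Boolean marker-positive flag per cell (expression >= threshold)."""
    if marker_gene not in mat.columns:
        raise KeyError(f"marker gene {marker_gene!r} not in matrix")
    return mat[marker_gene].astype(float) >= threshold


def coexpression_summary(
    mat: pd.DataFrame,
    marker_gene: str,
    candidates: Sequence[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-candidate co-expression counts and fractions with the marker.

    Candidate "expressing" uses the same threshold as the marker. Fractions
    are NaN when their denominator is zero (no expressing cells).
    """
    if not list(candidates):
        raise ValueError("candidate list must be non-empty")
    missing = [g for g in candidates if g not in mat.columns]
    if missing:
        raise KeyError(f"candidate gene(s) not in matrix: {missing}")
    validate_expression_matrix(mat)
    marker_pos = classify_cells(mat, marker_gene, threshold)
    n_marker = int(marker_pos.sum())
    rows = []
    for g in candidates:
        cand_pos = mat[g].astype(float) >= threshold
        n_exp = int(cand_pos.sum())
        n_co = int((cand_pos & marker_pos).sum())
        rows.append(
            {
                "gene": g,
                "n_expressing": n_exp,
                "n_coexpressing": n_co,
                "frac_candidate_pos_marker_pos": n_co / n_exp if n_exp else np.nan,
                "frac_marker_pos_candidate_pos": n_co / n_marker if n_marker else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a cells-rows x genes-columns TSV expression matrix."""
    return validate_expression_matrix(pd.read_csv(path, sep="\t", index_col=0))
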