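"""Per-cell-type miRNA expression summaries by discretization.

Normalized abundances are binned per miRNA into B equal-width levels over
that miRNA's own range (1 = lowest, B = highest), then summarized per cell
type by the lower median of member samples' levels.  B is the ceiling of the
cube root of the largest per-cell-type sample count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .omics_io import ExpressionMatrix, OmicsIOError

__all__ = [
    "DiscretizedAtlas",
    "n_bins",
    "discretize_abundances",
    "celltype_medians",
    "low_expression_filter",
    "build_atlas",
]


@dataclass
class DiscretizedAtlas:
    levels: pd.DataFrame  # miRNA × cell-type integer medians
    n_bins: int
    n_samples_per_type: dict[str, int]

    def __post_init__(self) -> None:
        arr = self.levels.to_numpy()
        if arr.size and ((arr < 1) | (arr > self.n_bins)).any():
            raise OmicsIOError("atlas levels outside 1..B")


def n_bins(samples_per_type: Mapping[str, int]) -> int:
    """``ceil(max(n) ** (1/3))`` over per-cell-type sample counts."""
    if not samples_per_type:
        raise OmicsIOError("empty sample-count map")
    n_max = max(samples_per_type.values())
    if n_max < 1:
        raise OmicsIOError("sample counts must be >= 1")
    # integer-safe cube root: avoid float error at exact cubes (e.g. 27)
    root = round(n_max ** (1.0 / 3.0))
    if root**3 == n_max:
        return int(root)
    return int(math.ceil(n_max ** (1.0 / 3.0)))


def discretize_abundances(
    mat: ExpressionMatrix, B: int, scheme: str = "width"
) -> pd.DataFrame:
    """Map each miRNA's values to integer levels 1..B.

    ``width`` (default) uses B equal-width bins spanning the miRNA's own
    [min, max]; ``quantile`` uses equal-count bins.  A constant miRNA maps
    to all 1s; row minima map to 1 and row maxima to B.
    """
    if B < 1:
        raise OmicsIOError("number of bins must be >= 1")
    values = mat.values.to_numpy(dtype=float)
    out = np.ones_like(values, dtype=int)
    for i in range(values.shape[0]):
        row = values[i]
        lo, hi = row.min(), row.max()
        if hi == lo:
            continue
        if scheme == "width":
            lev = np.floor((row - lo) / (hi - lo) * B).astype(int) + 1
        elif scheme == "quantile":
            edges = np.quantile(row, np.linspace(0, 1, B + 1)[1:-1])
            lev = np.searchsorted(edges, row, side="right") + 1
        else:
            raise OmicsIOError(f"unknown binning scheme {scheme!r}")
        out[i] = np.clip(lev, 1, B)
    return pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)


def _lower_median(vals: np.ndarray) -> int:
    s = np.sort(vals)
    return int(s[(len(s) - 1) // 2])


def celltype_medians(levels: pd.DataFrame, cell_labels: pd.Series) -> pd.DataFrame:
    """Per (miRNA, cell type) lower median of member samples' levels."""
    unlabeled = [s for s in levels.columns if s not in cell_labels.index]
    if unlabeled:
        raise OmicsIOError(f"samples without a cell-type label: {unlabeled}")
    types = sorted(pd.unique(cell_labels.loc[levels.columns]))
    out = {}
    for ct in types:
        cols = [s for s in levels.columns if cell_labels[s] == ct]
        if not cols:
            raise OmicsIOError(f"cell type {ct!r} has no samples")
        block = levels[cols].to_numpy()
        out[ct] = [_lower_median(block[i]) for i in range(block.shape[0])]
    return pd.DataFrame(out, index=levels.index)


def low_expression_filter(mat: ExpressionMatrix, min_count: int = 3) -> ExpressionMatrix:
    """Drop miRNAs whose count is below *min_count* in every sample."""
    if mat.kind != "counts":
        raise OmicsIOError("low_expression_filter requires counts")
    keep = mat.values.max(axis=1) >= min_count
    return ExpressionMatrix(mat.values.loc[keep], mat.sample_group, "counts")


def build_atlas(
    mat: ExpressionMatrix, cell_labels: pd.Series, scheme: str = "width"
) -> DiscretizedAtlas:
    """Discretize a normalized compendium and summarize per cell type."""
    counts_per_type = (
        cell_labels.loc[mat.sample_ids].value_counts().to_dict()
    )
    B = n_bins(counts_per_type)
    levels = discretize_abundances(mat, B, scheme=scheme)
    medians = celltype_medians(levels, cell_labels)
    return DiscretizedAtlas(medians, B, {str(k): int(v) for k, v in counts_per_type.items()})
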