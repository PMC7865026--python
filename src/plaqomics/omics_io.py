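"""Tabular I/O and preprocessing for expression matrices, cytokine panels
and gene-set maps.

Expression tables are TSV with feature IDs in the first column and one column
per sample.  Cytokine panels are wide TSV with ``subject`` and ``replicate``
columns followed by one column per analyte.  Gene sets use GMT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CytokinePanel",
    "read_expression_table",
    "write_expression_table",
    "filter_low_counts",
    "size_factors_median_of_ratios",
    "normalize_vst",
    "read_cytokine_panel",
    "write_cytokine_panel",
    "collapse_technical_replicates",
    "read_gene_sets",
    "write_gene_sets",
]


class OmicsIOError(ValueError):
    """Raised for malformed input tables."""


@dataclass
class ExpressionMatrix:
    """Feature × sample matrix of raw counts or normalized values.

    Parameters
    ----------
    values
        DataFrame with feature IDs as index, sample IDs as columns.
    sample_group
        Group label per sample (index = sample IDs).
    kind
        ``"counts"`` (non-negative integers) or ``"normalized"``.
    size_factors
        Per-sample scaling constants, attached by :func:`normalize_vst`.
    """

    values: pd.DataFrame
    sample_group: pd.Series
    kind: str = "counts"
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "normalized"):
            raise OmicsIOError(f"unknown matrix kind {self.kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise OmicsIOError(f"duplicate feature IDs: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise OmicsIOError(f"duplicate sample IDs: {dups}")
        missing = [s for s in cols if s not in self.sample_group.index]
        if missing:
            raise OmicsIOError(f"samples missing a group label: {missing}")
        self.sample_group = self.sample_group.reindex(cols)
        arr = self.values.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise OmicsIOError("matrix contains missing values")
        if (arr.astype(float) < 0).any():
            raise OmicsIOError("matrix contains negative values")
        if self.kind == "counts":
            farr = arr.astype(float)
            if not np.allclose(farr, np.round(farr)):
                raise OmicsIOError("count matrix contains non-integer values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise OmicsIOError(f"unknown samples: {missing}")
        sf = None
        if self.size_factors is not None:
            sf = self.size_factors.loc[samples]
        return ExpressionMatrix(
            self.values[samples], self.sample_group.loc[samples], self.kind, sf
        )

    def samples_in_groups(self, groups: list[str]) -> list[str]:
        return [s for s in self.values.columns if self.sample_group[s] in groups]


@dataclass
class CytokinePanel:
    """Sample × analyte abundances, optionally with technical replicate rows.

    Before collapse, ``values`` has one row per well with a unique well index
    and ``replicate_of`` maps wells to subjects.  After collapse, the index is
    the subject ID and ``replicate_of`` is ``None``.
    """

    values: pd.DataFrame
    replicate_of: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise OmicsIOError("duplicate row identifiers in cytokine panel")
        if self.replicate_of is None and (self.values.to_numpy() <= 0).any():
            raise OmicsIOError("collapsed cytokine panel must be strictly positive")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subjects(self) -> list[str]:
        if self.replicate_of is None:
            return list(self.values.index)
        return list(pd.unique(self.replicate_of))


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(
    path: str | Path, group_map: Mapping[str, str], kind: str = "counts"
) -> ExpressionMatrix:
    """Read a TSV expression table and attach group labels.

    The first column holds feature IDs, the header row sample IDs.  Duplicate
    IDs, non-numeric cells and samples absent from *group_map* are rejected
    with informative errors (non-numeric cells with their line number).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for i, (feat, row) in enumerate(df.iterrows()):
            for col, cell in row.items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    # +2: one for the header line, one for 1-based numbering
                    raise OmicsIOError(
                        f"{path.name}:{i + 2}: non-numeric cell {cell!r} "
                        f"for feature {feat!r}, sample {col!r}"
                    ) from None
        raise
    values.index.name = None
    missing = [s for s in values.columns if s not in group_map]
    if missing:
        raise OmicsIOError(f"samples missing from group map: {missing}")
    groups = pd.Series({s: group_map[s] for s in values.columns})
    return ExpressionMatrix(values, groups, kind=kind)


def write_expression_table(mat: ExpressionMatrix, path: str | Path) -> None:
    df = mat.values
    if mat.kind == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="feature_id")


def filter_low_counts(mat: ExpressionMatrix, min_count: int) -> ExpressionMatrix:
    """Drop features whose count is below *min_count* in every sample.

    A feature is retained iff its maximum count across samples is at least
    *min_count*; sample set and feature order are preserved.
    """
    if mat.kind != "counts":
        raise OmicsIOError("filter_low_counts requires a count matrix")
    if min_count < 1:
        raise OmicsIOError("min_count must be >= 1")
    keep = mat.values.max(axis=1) >= min_count
    return ExpressionMatrix(
        mat.values.loc[keep], mat.sample_group, "counts", mat.size_factors
    )


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over a geometric-mean pseudo-reference.

    The reference uses only features with strictly positive counts in all
    samples.  Factors are anchored to geometric mean 1, which makes them
    exactly equivariant: scaling one sample's counts by c scales its factor
    by c and leaves the others untouched.  A sample with no
    positive-reference features (e.g. all zeros) is an error.
    """
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise OmicsIOError("no feature has positive counts in every sample")
    log_ref = np.log(arr[all_pos]).mean(axis=1)
    sf = {}
    for j, sample in enumerate(counts.columns):
        col = arr[all_pos, j]
        if (col == 0).all():
            raise OmicsIOError(f"sample {sample!r} has all-zero counts")
        sf[sample] = float(np.exp(np.median(np.log(col) - log_ref)))
    out = pd.Series(sf)
    return out / np.exp(np.log(out).mean())


def normalize_vst(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size-corrected log transform: ``log2(count / sf + 1)``.

    Size factors are median-of-ratios; they are attached to the result.
    This is a monotone, rank-preserving stand-in for a closed-form
    variance-stabilizing transform.
    """
    if mat.kind != "counts":
        raise OmicsIOError("normalize_vst requires a count matrix")
    if mat.n_samples < 2:
        raise OmicsIOError("need at least two samples to normalize")
    zero_samples = mat.values.columns[(mat.values == 0).all(axis=0)]
    if len(zero_samples):
        raise OmicsIOError(f"sample {zero_samples[0]!r} has all-zero counts")
    sf = size_factors_median_of_ratios(mat.values)
    norm = np.log2(mat.values / sf + 1.0)
    return ExpressionMatrix(norm, mat.sample_group, "normalized", sf)


# ---------------------------------------------------------------------------
# cytokine panels


def read_cytokine_panel(path: str | Path) -> CytokinePanel:
    """Read a wide cytokine TSV with ``subject`` and ``replicate`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "replicate": str})
    for col in ("subject", "replicate"):
        if col not in df.columns:
            raise OmicsIOError(f"cytokine table missing {col!r} column")
    analytes = [c for c in df.columns if c not in ("subject", "replicate")]
    if not analytes:
        raise OmicsIOError("cytokine table has no analyte columns")
    wells = df["subject"] + "/" + df["replicate"]
    if wells.duplicated().any():
        raise OmicsIOError("duplicate (subject, replicate) rows")
    values = df[analytes].astype(float)
    values.index = wells
    return CytokinePanel(values, replicate_of=pd.Series(df["subject"].values, index=wells))


def write_cytokine_panel(panel: CytokinePanel, path: str | Path) -> None:
    df = panel.values.copy()
    if panel.replicate_of is not None:
        df.insert(0, "subject", panel.replicate_of.values)
        df.insert(1, "replicate", [w.rsplit("/", 1)[1] for w in panel.values.index])
    else:
        df.insert(0, "subject", panel.values.index)
        df.insert(1, "replicate", "1")
    df.to_csv(path, sep="\t", index=False)


def collapse_technical_replicates(panel: CytokinePanel) -> CytokinePanel:
    """Combine technical replicates per subject by geometric mean.

    Zeros are replaced by half the smallest positive value of the analyte
    before taking the geometric mean (the geometric mean is undefined at 0).
    """
    if panel.replicate_of is None:
        return panel
    values = panel.values.copy()
    for analyte in values.columns:
        col = values[analyte]
        if (col < 0).any():
            raise OmicsIOError(f"negative value for analyte {analyte!r}")
        if (col == 0).any():
            pos = col[col > 0]
            if pos.empty:
                raise OmicsIOError(f"analyte {analyte!r} is all-zero")
            values[analyte] = col.replace(0.0, float(pos.min()) / 2.0)
    logv = np.log(values)
    logv["__subject"] = panel.replicate_of.values
    collapsed = np.exp(logv.groupby("__subject", sort=False).mean())
    collapsed.index.name = None
    return CytokinePanel(collapsed, replicate_of=None)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into a name → member-set map.

    Each line: set name, description, then tab-separated members.  Empty sets
    and duplicate set names are rejected with line numbers.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise OmicsIOError(f"line {lineno}: gene set with no members")
            name = parts[0]
            if name in sets:
                raise OmicsIOError(f"line {lineno}: duplicate set name {name!r}")
            members = {p.strip() for p in parts[2:] if p.strip()}
            sets[name] = members
    return sets


def write_gene_sets(sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = sorted(sets[name])
            if not members:
                raise OmicsIOError(f"gene set {name!r} is empty")
            fh.write("\t".join([name, "na", *members]) + "\n")
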