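"""Single-subject transcription-factor activity scores.

For each TF, PCA is run on the subjects × target-genes submatrix of
normalized expression (genes mean-centered across subjects, unscaled).  With
``v_i`` the variance fraction of PC ``i``, ``s_ij`` the unweighted subject
coordinate on PC ``i`` and ``m`` the smallest PC index at which cumulative
variance (counting from PC1) reaches the threshold, the per-subject activity
score is::

    score_j = sqrt( sum_{i=2..m} s_ij^2 * v_i )

defined as 0 when ``m == 1``.  PC1 is excluded because it tracks
inter-individual variability in overall transcription level rather than
TF-specific variation.  Per-gene weights use the unit-norm loadings ``w_i``::

    raw_g = sqrt( sum_{i=2..m} w_gi^2 * v_i ) / (1 - v_1)

and are reported as percentages summing to 100 per TF (all 0 when m == 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .omics_io import CytokinePanel, ExpressionMatrix, OmicsIOError

__all__ = ["SPTFResult", "sptf_scores", "tf_gene_weights", "correlate_scores_with_cytokines"]

CUMVAR_THRESHOLD = 0.5


@dataclass
class SPTFResult:
    """Scores plus the PCA pieces they are built from.

    Attributes
    ----------
    scores : DataFrame, subjects × TFs, non-negative.
    m_per_tf : Series of PC cutoffs (smallest index with cumulative variance
        ≥ 50%, counting from PC1).
    variance_fractions : per-TF array of variance fractions summing to 1.
    pc_scores : per-TF DataFrame of unweighted subject PC coordinates.
    loadings : per-TF DataFrame (genes × PCs) of unit-norm loadings.
    gene_weights : per-TF Series of percent contributions summing to 100
        (all zero when m == 1).
    """

    scores: pd.DataFrame
    m_per_tf: pd.Series
    variance_fractions: dict[str, np.ndarray]
    pc_scores: dict[str, pd.DataFrame] = field(repr=False)
    loadings: dict[str, pd.DataFrame] = field(repr=False)
    gene_weights: dict[str, pd.Series] = field(default_factory=dict)


def _tf_pca(sub: np.ndarray):
    """Centered PCA of a subjects × genes block via SVD.

    Returns (pc_scores U*S, variance fractions, unit-norm loadings V).
    """
    centered = sub - sub.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    if total <= 1e-300:
        n, p = sub.shape
        k = min(n, p)
        return np.zeros((n, k)), np.full(k, np.nan), np.zeros((p, k))
    v_frac = s**2 / total
    return u * s, v_frac, vt.T


def sptf_scores(
    expr: ExpressionMatrix,
    tf_targets: dict[str, set[str]],
    cumvar_threshold: float = CUMVAR_THRESHOLD,
) -> SPTFResult:
    """Compute the per-subject activity score for every TF gene set.

    TFs with fewer than 2 expressed target genes are skipped with a warning;
    fewer than 3 subjects is an error.
    """
    if expr.kind != "normalized":
        raise OmicsIOError("sptf_scores expects normalized expression")
    if expr.n_samples < 3:
        raise OmicsIOError("need at least 3 subjects for PCA")
    subjects = expr.sample_ids
    expressed = set(expr.feature_ids)

    scores: dict[str, pd.Series] = {}
    m_per_tf: dict[str, int] = {}
    var_fracs: dict[str, np.ndarray] = {}
    pc_scores: dict[str, pd.DataFrame] = {}
    loadings: dict[str, pd.DataFrame] = {}
    weights: dict[str, pd.Series] = {}

    for tf in tf_targets:
        genes = sorted(tf_targets[tf] & expressed)
        if len(genes) < 2:
            warnings.warn(f"TF {tf!r}: fewer than 2 expressed targets, skipped")
            continue
        block = expr.values.loc[genes].to_numpy(dtype=float).T  # subjects × genes
        s_mat, v_frac, load = _tf_pca(block)
        if np.isnan(v_frac).all():  # constant submatrix
            m = 1
            scores[tf] = pd.Series(0.0, index=subjects)
            weights[tf] = pd.Series(0.0, index=genes)
            m_per_tf[tf] = m
            var_fracs[tf] = v_frac
            pc_scores[tf] = pd.DataFrame(s_mat, index=subjects)
            loadings[tf] = pd.DataFrame(load, index=genes)
            continue
        cum = np.cumsum(v_frac)
        m = int(np.searchsorted(cum, cumvar_threshold - 1e-12) + 1)
        m = min(m, len(v_frac))
        if m == 1:
            sc = np.zeros(len(subjects))
            w = np.zeros(len(genes))
        else:
            sl = slice(1, m)
            sc = np.sqrt((s_mat[:, sl] ** 2 * v_frac[sl]).sum(axis=1))
            raw = np.sqrt((load[:, sl] ** 2 * v_frac[sl]).sum(axis=1)) / (1.0 - v_frac[0])
            tot = raw.sum()
            w = raw / tot * 100.0 if tot > 0 else np.zeros_like(raw)
        scores[tf] = pd.Series(sc, index=subjects)
        weights[tf] = pd.Series(w, index=genes)
        m_per_tf[tf] = m
        var_fracs[tf] = v_frac
        pc_scores[tf] = pd.DataFrame(s_mat, index=subjects)
        loadings[tf] = pd.DataFrame(load, index=genes)

    if not scores:
        raise OmicsIOError("no TF had at least 2 expressed target genes")
    return SPTFResult(
        scores=pd.DataFrame(scores),
        m_per_tf=pd.Series(m_per_tf, dtype=int),
        variance_fractions=var_fracs,
        pc_scores=pc_scores,
        loadings=loadings,
        gene_weights=weights,
    )


def tf_gene_weights(result: SPTFResult) -> pd.DataFrame:
    """Long-format per-TF gene weights (percent contributions)."""
    rows = []
    for tf, w in result.gene_weights.items():
        for gene, val in w.items():
            rows.append((tf, gene, float(val)))
    return pd.DataFrame(rows, columns=["tf", "gene", "weight_pct"])


def correlate_scores_with_cytokines(
    result: SPTFResult, panel: CytokinePanel, p_star: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of every TF score with every analyte.

    Computed over the subjects common to scores and panel (≥4 required).
    Constant vectors yield missing ``r`` rather than 0.  ``significant`` is
    the raw p < ``p_star`` flag; no multiplicity correction is applied.
    """
    if panel.replicate_of is not None:
        raise OmicsIOError("collapse technical replicates before correlating")
    common = [s for s in result.scores.index if s in panel.values.index]
    if len(common) < 4:
        raise OmicsIOError("fewer than 4 subjects shared between scores and panel")
    rows = []
    for tf in result.scores.columns:
        x = result.scores.loc[common, tf].to_numpy(dtype=float)
        for analyte in panel.values.columns:
            y = panel.values.loc[common, analyte].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((tf, analyte, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((tf, analyte, float(r), float(p), bool(p < p_star)))
    return pd.DataFrame(rows, columns=["tf", "analyte", "r", "p", "significant"])
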