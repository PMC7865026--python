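"""Negative-binomial Wald tests for two-group contrasts.

The model is a per-feature NB GLM with log link and size-factor offsets:
``count_ij ~ NB(mean = q_g(i) * s_j, variance = mu + alpha_i * mu^2)``.
Group means are fit by Fisher scoring (vectorized across features), the Wald
statistic is the contrast log fold change over its standard error, and
p-values are BH-adjusted.  No shrinkage, independent filtering or outlier
replacement is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .omics_io import ExpressionMatrix, OmicsIOError, size_factors_median_of_ratios

__all__ = [
    "DEResult",
    "estimate_dispersions",
    "nb_wald_test",
    "apply_de_thresholds",
    "benjamini_hochberg",
]

_LN2 = np.log(2.0)


@dataclass
class DEResult:
    feature_id: str
    log2fc: float
    se: float
    p: float
    padj: float


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment; NaN inputs propagate to NaN outputs."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _group_normalized(mat: ExpressionMatrix, size_factors: pd.Series) -> pd.DataFrame:
    return mat.values / size_factors


def _dispersion_trend(means: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Parametric trend ``a0 + a1 / mean`` fit to positive raw estimates."""
    ok = (raw > 0) & (means > 0)
    if ok.sum() < 3:
        med = float(np.median(raw[raw > 0])) if (raw > 0).any() else 0.0
        return np.full_like(raw, med)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(means > 0, means, np.nan)
    trend = np.where(np.isfinite(trend), trend, 0.0)
    return np.clip(trend, 0.0, None)


def estimate_dispersions(mat: ExpressionMatrix, groups: list[str] | None = None) -> pd.Series:
    """Per-feature NB dispersion by method of moments with trend shrinkage.

    Within-group residual variance of size-factor-normalized counts gives a
    raw moment estimate ``alpha = (var - mean) / mean^2`` (clipped at 0),
    which is averaged 50/50 with a parametric trend over mean expression.
    """
    if mat.kind != "counts":
        raise OmicsIOError("dispersion estimation requires counts")
    labels = mat.sample_group
    use_groups = groups if groups is not None else list(pd.unique(labels))
    samples = mat.samples_in_groups(use_groups)
    sub = mat.subset_samples(samples)
    counts = sub.values
    for g in use_groups:
        n_g = int((sub.sample_group == g).sum())
        if n_g < 2:
            raise OmicsIOError(f"group {g!r} has fewer than 2 samples")
    sf = sub.size_factors
    if sf is None:
        sf = size_factors_median_of_ratios(counts)
    q = _group_normalized(sub, sf)

    grand_mean = q.mean(axis=1).to_numpy()
    # pooled within-group residual variance
    ss = np.zeros(sub.n_features)
    dof = 0
    for g in use_groups:
        cols = sub.sample_group[sub.sample_group == g].index
        block = q[cols].to_numpy()
        mu_g = block.mean(axis=1, keepdims=True)
        ss += ((block - mu_g) ** 2).sum(axis=1)
        dof += len(cols) - 1
    var = ss / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - grand_mean) / np.where(grand_mean > 0, grand_mean**2, np.nan)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, 0.0, None)
    trend = _dispersion_trend(grand_mean, raw)
    alpha = 0.5 * raw + 0.5 * trend
    return pd.Series(np.clip(alpha, 0.0, None), index=counts.index, name="alpha")


def _fit_group_log_mean(
    counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher scoring for ``log q`` in ``mu_ij = q_i * s_j`` per feature.

    Returns the natural-log group abundance and the Fisher information.
    Features with all-zero counts get ``beta = -inf`` and information 0.
    """
    total = counts.sum(axis=1)
    with np.errstate(divide="ignore"):
        beta = np.log(total / sf.sum())
    zero = total == 0
    beta[zero] = -np.inf
    live = ~zero
    b = beta[live].copy()
    k = counts[live]
    a = alpha[live][:, None]
    for _ in range(max_iter):
        mu = np.exp(b)[:, None] * sf[None, :]
        denom = 1.0 + a * mu
        score = ((k - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.where(info > 0, info, 1.0)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    beta[live] = b
    info_full = np.zeros_like(beta)
    mu = np.exp(b)[:, None] * sf[None, :]
    info_full[live] = (mu / (1.0 + a * mu)).sum(axis=1)
    return beta, info_full


def nb_wald_test(
    mat: ExpressionMatrix,
    contrast: tuple[str, str],
    alpha: pd.Series | None = None,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test of ``contrast[0]`` versus ``contrast[1]``.

    Returns a DataFrame with columns ``log2fc``, ``se``, ``p``, ``padj``
    indexed by feature, sorted by feature ID for determinism.  ``log2fc`` is
    positive when the feature is higher in ``contrast[0]``.  Features with
    all-zero counts in both groups get NaN statistics and are excluded from
    the BH adjustment.
    """
    if mat.kind != "counts":
        raise OmicsIOError("nb_wald_test requires counts")
    g_a, g_b = contrast
    for g in (g_a, g_b):
        if g not in set(mat.sample_group):
            raise OmicsIOError(f"unknown group label {g!r}")
    samples = mat.samples_in_groups([g_a, g_b])
    sub = mat.subset_samples(samples)
    if size_factors is None:
        size_factors = sub.size_factors
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(sub.values)
    size_factors = size_factors.loc[samples]
    if alpha is None:
        alpha = estimate_dispersions(sub, [g_a, g_b])
    alpha_arr = alpha.reindex(sub.values.index).to_numpy(dtype=float)
    if np.isnan(alpha_arr).any():
        raise OmicsIOError("dispersion missing for some features")

    cols_a = [s for s in samples if sub.sample_group[s] == g_a]
    cols_b = [s for s in samples if sub.sample_group[s] == g_b]
    k_a = sub.values[cols_a].to_numpy(dtype=float)
    k_b = sub.values[cols_b].to_numpy(dtype=float)
    sf_a = size_factors.loc[cols_a].to_numpy(dtype=float)
    sf_b = size_factors.loc[cols_b].to_numpy(dtype=float)

    beta_a, info_a = _fit_group_log_mean(k_a, sf_a, alpha_arr)
    beta_b, info_b = _fit_group_log_mean(k_b, sf_b, alpha_arr)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = (beta_a - beta_b) / _LN2
        se = np.sqrt(1.0 / info_a + 1.0 / info_b) / _LN2
        z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    bad = ~np.isfinite(lfc) | ~np.isfinite(se)
    lfc = np.where(bad, np.nan, lfc)
    se = np.where(bad, np.nan, se)
    p = np.where(bad, np.nan, p)

    res = pd.DataFrame(
        {"log2fc": lfc, "se": se, "p": p}, index=sub.values.index
    ).sort_index(kind="stable")
    res["padj"] = benjamini_hochberg(res["p"].to_numpy())
    res.index.name = "feature_id"
    return res


def apply_de_thresholds(
    results: pd.DataFrame, padj_max: float, lfc_min: float
) -> pd.DataFrame:
    """Keep features with ``padj < padj_max`` and ``|log2fc| > lfc_min``."""
    if results.empty:
        return results
    keep = (results["padj"] < padj_max) & (results["log2fc"].abs() > lfc_min)
    return results.loc[keep.fillna(False)]
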