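"""miRNA-target integration: prediction aggregation, expression
anticorrelation filtering, LDA discriminant gene selection, miRNA-cytokine
correlation and fold-change quadrant bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .omics_io import CytokinePanel, ExpressionMatrix, OmicsIOError

__all__ = [
    "PREDICTION_ALGORITHMS",
    "DiscriminantSelection",
    "aggregate_target_predictions",
    "anticorrelation_filter",
    "lda_discriminant_genes",
    "mirna_cytokine_correlation",
    "fold_change_quadrants",
    "stars_for_p",
]

#: the five source prediction algorithms whose votes make up `support`
PREDICTION_ALGORITHMS = frozenset({"diana", "miranda", "targetscan", "pictar", "mirdb"})


def aggregate_target_predictions(
    raw: pd.DataFrame,
    min_support: int = 2,
    algorithms: frozenset[str] = PREDICTION_ALGORITHMS,
) -> pd.DataFrame:
    """Count distinct supporting algorithms per (miRNA, gene) pair and keep
    pairs with support >= *min_support*.

    *raw* needs columns ``mirna``, ``gene``, ``algorithm``; repeat votes by
    the same algorithm count once; unknown algorithm labels are an error.
    """
    for col in ("mirna", "gene", "algorithm"):
        if col not in raw.columns:
            raise OmicsIOError(f"prediction table missing {col!r} column")
    unknown = set(raw["algorithm"]) - set(algorithms)
    if unknown:
        raise OmicsIOError(f"unknown prediction algorithm(s): {sorted(unknown)}")
    dedup = raw.drop_duplicates(subset=["mirna", "gene", "algorithm"])
    support = (
        dedup.groupby(["mirna", "gene"], sort=True)
        .size()
        .rename("support")
        .reset_index()
    )
    return support[support["support"] >= min_support].reset_index(drop=True)


def anticorrelation_filter(
    targets: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    r_max: float = -0.5,
    p_max: float = 0.05,
    method: str = "pearson",
) -> pd.DataFrame:
    """Keep predicted pairs whose expression is significantly anticorrelated.

    Correlation is computed over the samples common to both matrices
    (at least 4 required); a pair is retained iff ``r <= r_max`` and
    ``p < p_max``.  Pairs with a feature missing from either matrix are
    dropped.  Returns the table with ``r`` and ``p`` columns added.
    """
    common = [s for s in mirna_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(common) < 4:
        raise OmicsIOError("fewer than 4 samples shared between miRNA and mRNA")
    mir = mirna_expr.values[common]
    mrna = mrna_expr.values[common]
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise OmicsIOError(f"unknown correlation method {method!r}")

    rows = []
    for rec in targets.itertuples(index=False):
        if rec.mirna not in mir.index or rec.gene not in mrna.index:
            continue
        x = mir.loc[rec.mirna].to_numpy(dtype=float)
        y = mrna.loc[rec.gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r, p = corr(x, y)
        if r <= r_max and p < p_max:
            rows.append((*rec, float(r), float(p)))
    return pd.DataFrame(rows, columns=[*targets.columns, "r", "p"])


@dataclass
class DiscriminantSelection:
    """Top-k genes by absolute standardized LDA coefficient."""

    ranked: pd.Series  # gene -> |standardized coefficient|, descending
    selected: list[str]
    projection: pd.Series  # sample -> discriminant value (k-gene re-fit)
    separated: bool
    coefficients: pd.Series = field(repr=False, default=None)


def _lda_direction(X: np.ndarray, y: np.ndarray, shrinkage: float) -> np.ndarray:
    """Two-class LDA direction with diagonal-shrunk within-class covariance."""
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    resid = np.vstack([X[y == 0] - mu0, X[y == 1] - mu1])
    cov = resid.T @ resid / max(len(X) - 2, 1)
    diag = np.diag(np.diag(cov))
    reg = (1.0 - shrinkage) * cov + shrinkage * diag
    # tiny ridge keeps the solve well-posed when genes are constant
    reg += np.eye(len(reg)) * 1e-10 * max(np.trace(reg) / len(reg), 1e-12)
    return np.linalg.solve(reg, mu1 - mu0)


def lda_discriminant_genes(
    expr: ExpressionMatrix,
    labels: pd.Series,
    k: int = 27,
    shrinkage: float = 0.5,
) -> DiscriminantSelection:
    """Rank genes by |standardized LDA coefficient| and select the top *k*.

    The within-class covariance is shrunk toward its diagonal
    (``(1-λ)Σ + λ diag(Σ)``, default λ=0.5) to keep the small-n/large-p
    solve well-posed.  Coefficients are standardized by the within-class
    standard deviation of each gene so the ranking is invariant to affine
    rescaling of any single gene.  ``separated`` is True iff re-fitting on
    the selected genes projects the two classes with no overlap.
    """
    classes = sorted(pd.unique(labels.loc[expr.sample_ids]))
    if len(classes) != 2:
        raise OmicsIOError(f"LDA needs exactly 2 classes, got {classes}")
    y = (labels.loc[expr.sample_ids] == classes[1]).to_numpy().astype(int)
    if (y == 0).sum() < 3 or (y == 1).sum() < 3:
        raise OmicsIOError("need at least 3 samples per class")
    genes = sorted(expr.feature_ids)
    X = expr.values.loc[genes].to_numpy(dtype=float).T  # samples × genes

    beta = _lda_direction(X, y, shrinkage)
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    resid = np.vstack([X[y == 0] - mu0, X[y == 1] - mu1])
    sd = resid.std(axis=0, ddof=1)
    standardized = pd.Series(np.abs(beta) * sd, index=genes)
    ranked = standardized.sort_values(ascending=False, kind="stable")
    selected = list(ranked.index[: min(k, len(genes))])

    sel_idx = [genes.index(g) for g in selected]
    beta_k = _lda_direction(X[:, sel_idx], y, shrinkage)
    proj = pd.Series(X[:, sel_idx] @ beta_k, index=expr.sample_ids)
    p0, p1 = proj[y == 0], proj[y == 1]
    separated = bool(p0.max() < p1.min() or p1.max() < p0.min())
    return DiscriminantSelection(
        ranked=ranked,
        selected=selected,
        projection=proj,
        separated=separated,
        coefficients=pd.Series(beta, index=genes),
    )


def stars_for_p(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.005, *** p<0.001."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def mirna_cytokine_correlation(
    mirna_expr: ExpressionMatrix, panel: CytokinePanel
) -> pd.DataFrame:
    """Spearman rho and p for every (miRNA, analyte) pair over shared samples."""
    if panel.replicate_of is not None:
        raise OmicsIOError("collapse technical replicates before correlating")
    common = [s for s in mirna_expr.sample_ids if s in panel.values.index]
    if len(common) < 4:
        raise OmicsIOError("fewer than 4 samples shared with the cytokine panel")
    rows = []
    for mirna in mirna_expr.feature_ids:
        x = mirna_expr.values.loc[mirna, common].to_numpy(dtype=float)
        for analyte in panel.values.columns:
            y = panel.values.loc[common, analyte].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((mirna, analyte, "spearman", np.nan, np.nan, ""))
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append((mirna, analyte, "spearman", float(rho), float(p), stars_for_p(p)))
    return pd.DataFrame(rows, columns=["x_id", "y_id", "method", "r", "p", "stars"])


def fold_change_quadrants(
    de_a: pd.DataFrame, de_b: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Sign quadrant of each gene's (contrast A, contrast B) fold changes.

    Quadrants are ``up/up``, ``up/down``, ``down/up``, ``down/down``; a zero
    fold change in either contrast gives ``null``.  Genes missing from either
    result are labeled ``missing`` and excluded from quadrant counts.
    """
    rows = []
    for gene in genes:
        if gene not in de_a.index or gene not in de_b.index:
            rows.append((gene, np.nan, np.nan, "missing"))
            continue
        fa = float(de_a.loc[gene, "log2fc"])
        fb = float(de_b.loc[gene, "log2fc"])
        if fa == 0 or fb == 0 or np.isnan(fa) or np.isnan(fb):
            quad = "null"
        else:
            quad = ("up" if fa > 0 else "down") + "/" + ("up" if fb > 0 else "down")
        rows.append((gene, fa, fb, quad))
    return pd.DataFrame(rows, columns=["gene", "log2fc_a", "log2fc_b", "quadrant"])
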