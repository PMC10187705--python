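"""Composite sample scoring and cluster stratification.

Two composite scores over a signature gene panel:

* RISK score — sum_i x_i * beta_i, with beta from a two-class linear
  discriminant (binary clinical parameters) or a Cox fit (survival).
* PCA aging score — genes are z-standardized, the correlation matrix is
  eigen-decomposed, components with eigenvalue E_j > 1 are kept, each
  gene receives the weight W_i = sum_j L_ij * E_j over the kept
  components, and each sample scores sum_i z_si * W_i / sum_i W_i.  The
  training-score mean is 0 by construction, and the sign of the score
  splits samples into a more-aggressive (score > 0) and a less-aggressive
  (score <= 0) cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RiskScoreModel",
    "PCAAgingModel",
    "ClusterAssignment",
    "fit_lda",
    "risk_score",
    "fit_pca_aging",
    "pca_aging_score",
    "stratify",
]


@dataclass
class RiskScoreModel:
    """Per-gene coefficients of a beta-weighted composite risk score."""

    parameter: str
    coefficients: pd.Series  # indexed by gene, fixed order

    def __post_init__(self):
        if not np.all(np.isfinite(self.coefficients.to_numpy(dtype=float))):
            raise ValueError("coefficients must be finite")


def fit_lda(x: pd.DataFrame, y, ridge: float = 1e-6) -> pd.Series:
    """Two-class linear-discriminant direction, ridge-stabilized.

    beta = (S_w + ridge * tr(S_w)/p * I)^-1 (mu_1 - mu_0) with S_w the
    pooled within-class covariance.  Deterministic; equivariant under
    gene permutation.
    """
    X = x.to_numpy(dtype=float)
    yb = pd.Series(np.asarray(y)).astype(str).to_numpy()
    levels = sorted(pd.unique(yb))
    if len(levels) != 2:
        raise ValueError("y must contain exactly two classes")
    X0 = X[yb == levels[0]]
    X1 = X[yb == levels[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs >= 2 samples")
    p = X.shape[1]
    sw = (
        (len(X0) - 1) * np.cov(X0, rowvar=False).reshape(p, p)
        + (len(X1) - 1) * np.cov(X1, rowvar=False).reshape(p, p)
    ) / (len(X0) + len(X1) - 2)
    scale = np.trace(sw) / p if np.trace(sw) > 0 else 1.0
    beta = np.linalg.solve(sw + ridge * scale * np.eye(p), X1.mean(axis=0) - X0.mean(axis=0))
    return pd.Series(beta, index=x.columns, name="beta")


def risk_score(expr: pd.DataFrame, model: RiskScoreModel) -> pd.Series:
    """Per-sample dot product of expression with the model coefficients.

    ``expr`` is sample x gene; genes must cover the model's gene order.
    """
    missing = model.coefficients.index.difference(expr.columns)
    if len(missing):
        raise KeyError(f"expression matrix lacks model genes: {list(missing)}")
    aligned = expr[model.coefficients.index].to_numpy(dtype=float)
    return pd.Series(
        aligned @ model.coefficients.to_numpy(dtype=float),
        index=expr.index,
        name=f"risk_{model.parameter}",
    )


@dataclass
class PCAAgingModel:
    """Standardization constants, loadings, eigenvalues and gene weights."""

    means: pd.Series
    sds: pd.Series
    loadings: pd.DataFrame      # gene x component, kept components only
    eigenvalues: pd.Series      # kept components only (all > 1)
    weights: pd.Series          # W_i = sum_j L_ij * E_j
    all_eigenvalues: pd.Series = field(default=None)

    def __post_init__(self):
        if (self.eigenvalues <= 1).any():
            raise ValueError("kept components must all have eigenvalue > 1")
        if abs(float(self.weights.sum())) < 1e-12:
            raise ValueError("degenerate panel: gene weights sum to zero")


@dataclass
class ClusterAssignment:
    labels: pd.Series  # per-sample cluster label
    scores: pd.Series


def fit_pca_aging(
    expr_panel: pd.DataFrame, first_pc_only: bool = False
) -> PCAAgingModel:
    """Fit the eigenvalue-weighted PCA score on a sample x gene panel.

    Genes are z-standardized; the correlation matrix is
    eigen-decomposed; only components with eigenvalue > 1 are kept (an
    error if none qualifies — e.g. a single-gene panel, whose sole
    eigenvalue is exactly 1).  Each kept component is oriented so that
    its loading sum is positive, making "higher score = higher panel
    expression" stable across runs.  ``first_pc_only`` restricts the
    weight sum to the leading kept component.
    """
    if expr_panel.shape[1] < 2:
        raise ValueError("panel must contain at least 2 genes")
    if expr_panel.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    X = expr_panel.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.where(sds == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance genes in panel: {list(expr_panel.columns[zero])}"
        )
    Z = (X - means) / sds
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)
    keep = np.where(evals > 1.0)[0]
    if keep.size == 0:
        raise ValueError("degenerate panel: no component with eigenvalue > 1")
    if first_pc_only:
        keep = keep[:1]
    L = evecs[:, keep]
    # orient: loading sum positive per component
    signs = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    L = L * signs[None, :]
    E = evals[keep]
    W = L @ E
    comp_names = [f"PC{j + 1}" for j in keep]
    genes = expr_panel.columns
    return PCAAgingModel(
        means=pd.Series(means, index=genes, name="mean"),
        sds=pd.Series(sds, index=genes, name="sd"),
        loadings=pd.DataFrame(L, index=genes, columns=comp_names),
        eigenvalues=pd.Series(E, index=comp_names, name="eigenvalue"),
        weights=pd.Series(W, index=genes, name="weight"),
        all_eigenvalues=pd.Series(
            evals, index=[f"PC{j + 1}" for j in range(evals.size)], name="eigenvalue"
        ),
    )


def pca_aging_score(expr_panel: pd.DataFrame, model: PCAAgingModel) -> pd.Series:
    """score_s = sum_i z_si * W_i / sum_i W_i, using training means/SDs."""
    missing = model.weights.index.difference(expr_panel.columns)
    if len(missing):
        raise KeyError(f"expression matrix lacks panel genes: {list(missing)}")
    X = expr_panel[model.weights.index].to_numpy(dtype=float)
    Z = (X - model.means.to_numpy()) / model.sds.to_numpy()
    wsum = float(model.weights.sum())
    if abs(wsum) < 1e-12:
        raise ValueError("gene weights sum to zero")
    return pd.Series(
        Z @ model.weights.to_numpy() / wsum, index=expr_panel.index, name="pca_aging_score"
    )


def stratify(scores: pd.Series, mode: str = "aging") -> ClusterAssignment:
    """Sign-of-score stratification into more/less aggressive clusters.

    score > 0 -> MAAC (aging mode) / MAYC (young mode); score <= 0 ->
    LAAC / LAYC.  A score of exactly 0 (a sample at every gene mean)
    falls in the less-aggressive cluster.
    """
    s = pd.Series(scores, dtype=float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("scores must be finite")
    if mode == "aging":
        hi, lo = "MAAC", "LAAC"
    elif mode == "young":
        hi, lo = "MAYC", "LAYC"
    else:
        raise ValueError("mode must be 'aging' or 'young'")
    labels = pd.Series(np.where(s > 0, hi, lo), index=s.index, name="cluster")
    return ClusterAssignment(labels=labels, scores=s)
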