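"""Differential expression by negative-binomial GLM likelihood-ratio test.

Per-gene NB2 GLM with log link and a library-size offset, fitted under a
full and a nested reduced design; the test statistic is 2*(llf_full -
llf_reduced) against a chi-square with df equal to the parameter
difference.  Dispersion is a per-gene method-of-moments estimate with a
floor, optionally shrunk toward the abundance trend — a deliberately
simple, documented estimator rather than a re-implementation of any
particular dispersion-shrinkage machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "DesignSpec",
    "DEResult",
    "bh_adjust",
    "nb_glm_lrt",
    "select_degs",
    "cohort_specific_sets",
]

_LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame, method: str = "median_ratio") -> np.ndarray:
    """Per-sample library-size factors, geometric-mean normalized.

    ``median_ratio`` (default) is the median-of-ratios estimator — each
    sample's median ratio to the per-gene geometric mean across samples —
    which is robust to asymmetric composition (a block of strongly
    induced genes does not drag the other genes' apparent expression
    down).  ``total`` uses plain total counts.
    """
    arr = counts.to_numpy(dtype=float)
    if method == "total":
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total count")
        return totals / np.exp(np.mean(np.log(totals)))
    if method != "median_ratio":
        raise ValueError(f"unknown normalization {method!r}")
    with np.errstate(divide="ignore"):
        log_geo = np.mean(np.log(arr), axis=1)
    ok = np.isfinite(log_geo)
    if ok.sum() < 10:  # too few all-positive genes: fall back
        return size_factors(counts, method="total")
    ratios = np.log(arr[ok]) - log_geo[ok, None]
    sf = np.exp(np.median(ratios, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


@dataclass(frozen=True)
class DesignSpec:
    """A two-level contrast plus adjustment covariates.

    ``contrast`` names a clinical column with exactly two levels among the
    analysed samples; ``reference`` optionally pins the baseline level
    (default: lexicographically first).  ``covariates`` are additional
    clinical columns; categorical columns are dummy-coded dropping the
    first level, numeric columns enter linearly.  ``contrast=None`` gives
    an intercept-plus-covariates (reduced) design.
    """

    contrast: str | None
    covariates: tuple = ()
    reference: str | None = None

    def reduced(self) -> "DesignSpec":
        return DesignSpec(contrast=None, covariates=self.covariates)


def _encode_column(col: pd.Series) -> pd.DataFrame:
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float).to_frame()
    dummies = pd.get_dummies(col.astype(str), prefix=col.name, drop_first=True)
    return dummies.astype(float)


def build_design(clinical: pd.DataFrame, spec: DesignSpec) -> tuple[np.ndarray, list]:
    """Design matrix (with intercept first, contrast second if present)."""
    cols = [pd.Series(1.0, index=clinical.index, name="intercept").to_frame()]
    names = ["intercept"]
    if spec.contrast is not None:
        levels = sorted(clinical[spec.contrast].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(
                f"contrast {spec.contrast!r} must have exactly 2 levels, "
                f"found {levels}"
            )
        ref = spec.reference if spec.reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among {levels}")
        alt = [l for l in levels if l != ref][0]
        ind = (clinical[spec.contrast].astype(str) == alt).astype(float)
        cols.append(ind.rename(f"{spec.contrast}[{alt}]").to_frame())
        names.append(f"{spec.contrast}[{alt}]")
    for cov in spec.covariates:
        enc = _encode_column(clinical[cov])
        # drop covariate columns collinear with what we already have
        cols.append(enc)
        names.extend(enc.columns)
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    # prune exactly collinear columns (keeps the earliest occurrence)
    keep = []
    for j in range(X.shape[1]):
        sub = X[:, keep + [j]]
        if np.linalg.matrix_rank(sub) == len(keep) + 1:
            keep.append(j)
    return X[:, keep], [names[j] for j in keep]


# ----------------------------------------------------------------------
# NB GLM fitting

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    inv = 1.0 / alpha
    mu = np.maximum(mu, 1e-10)
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float, bool]:
    """IRLS for an NB2 GLM with log link and known dispersion.

    Returns (beta, loglik, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    ll_old = -np.inf
    converged = False
    ridge = 1e-8
    for _ in range(max_iter):
        eta = offset + X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-10)
        Xw = X * w[:, None]
        A = X.T @ Xw + ridge * np.eye(p)
        b = Xw.T @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return beta, _nb_loglik(y, mu, alpha), False
        ll = _nb_loglik(y, np.exp(np.clip(offset + X @ beta_new, -30, 30)), alpha)
        # step-halving if the likelihood drops
        step = 1.0
        while ll < ll_old - 1e-10 and step > 1e-4:
            step /= 2.0
            trial = beta + step * (beta_new - beta)
            ll = _nb_loglik(y, np.exp(np.clip(offset + X @ trial, -30, 30)), alpha)
            beta_new = trial
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            beta = beta_new
            converged = True
            break
        beta, ll_old = beta_new, ll
    eta = np.clip(offset + X @ beta, -30, 30)
    return beta, _nb_loglik(y, np.exp(eta), alpha), converged


def estimate_dispersions(
    counts: pd.DataFrame,
    group: pd.Series,
    size_factors: np.ndarray,
    floor: float = 1e-4,
    shrink_weight: float = 0.0,
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion, pooled within groups.

    On size-factor-normalized counts, within each level of ``group``:
    alpha_hat = sum_k (n_k-1)(s2_k - m_k) / sum_k (n_k-1) m_k^2, floored.
    ``shrink_weight`` in [0, 1] optionally pulls each estimate toward the
    median dispersion of genes with similar abundance (a crude trend).
    """
    norm = counts.to_numpy(dtype=float) / size_factors[None, :]
    g = np.asarray(group.astype(str))
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for level in np.unique(g):
        sub = norm[:, g == level]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        w = sub.shape[1] - 1
        num += w * (s2 - m)
        den += w * np.maximum(m, 1e-8) ** 2
    alpha = np.maximum(num / np.maximum(den, 1e-12), floor)
    if shrink_weight > 0:
        mean_all = norm.mean(axis=1)
        order = np.argsort(mean_all)
        trend = np.empty_like(alpha)
        # rolling-median trend over abundance rank
        half = max(10, counts.shape[0] // 50)
        sorted_alpha = alpha[order]
        for i in range(alpha.size):
            lo, hi = max(0, i - half), min(alpha.size, i + half + 1)
            trend[order[i]] = np.median(sorted_alpha[lo:hi])
        alpha = (1 - shrink_weight) * alpha + shrink_weight * trend
    return alpha


@dataclass
class DEResult:
    """Per-gene contrast effect, LRT p-values and status flags."""

    table: pd.DataFrame  # columns: log2fc, pvalue, padj, mean_count, flag
    contrast: str = ""
    covariates: tuple = ()

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up; NaNs are passed through untested."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def nb_glm_lrt(
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    design_full: DesignSpec,
    design_reduced: DesignSpec | None = None,
    min_count: int = 10,
    dispersion: float | np.ndarray | None = None,
    dispersion_groups: pd.Series | None = None,
    dispersion_floor: float = 1e-4,
    shrink_weight: float = 0.0,
    normalization: str = "median_ratio",
    precomputed_size_factors: np.ndarray | None = None,
) -> DEResult:
    """Likelihood-ratio test of the contrast term, gene by gene.

    The reduced design defaults to the full design without its contrast.
    Genes with total count below ``min_count`` are flagged ``low_count``
    and excluded from testing (p-values NA).  Library-size offsets are
    log median-of-ratios size factors (``normalization="total"`` uses
    total counts).  ``dispersion_groups`` optionally names a finer sample
    grouping for the method-of-moments dispersion estimate than the
    contrast levels — useful when a known structural factor (e.g. age
    group) would otherwise be absorbed into the dispersion.
    """
    if design_full.contrast is None:
        raise ValueError("full design must contain a contrast")
    if design_reduced is None:
        design_reduced = design_full.reduced()
    if design_reduced.contrast == design_full.contrast:
        raise ValueError("reduced design must not contain the tested contrast")
    if set(design_reduced.covariates) - set(design_full.covariates):
        raise ValueError("reduced design is not nested in the full design")
    clinical = clinical.loc[counts.columns]
    level_counts = clinical[design_full.contrast].astype(str).value_counts()
    if len(level_counts) != 2 or level_counts.min() < 2:
        raise ValueError(
            "contrast requires exactly two levels with >= 2 samples each"
        )

    Xf, names_f = build_design(clinical, design_full)
    Xr, _ = build_design(clinical, design_reduced)
    df = Xf.shape[1] - Xr.shape[1]
    if df < 1:
        raise ValueError("full design does not extend the reduced design")
    contrast_col = 1  # intercept first, contrast indicator second

    y_all = counts.to_numpy(dtype=float)
    if (y_all.sum(axis=0) <= 0).any():
        raise ValueError("a sample has zero total count")
    if precomputed_size_factors is not None:
        sf = np.asarray(precomputed_size_factors, dtype=float)
        if sf.shape != (counts.shape[1],) or (sf <= 0).any():
            raise ValueError("size factors must be positive, one per sample")
    else:
        # note: when testing a gene subset, pass size factors computed on
        # the full matrix — a subset of co-regulated genes would absorb
        # the tested signal into the offset
        sf = size_factors(counts, method=normalization)
    offset = np.log(sf)

    if dispersion is None:
        group = (
            dispersion_groups.loc[counts.columns]
            if dispersion_groups is not None
            else clinical[design_full.contrast]
        )
        alphas = estimate_dispersions(
            counts,
            group,
            sf,
            floor=dispersion_floor,
            shrink_weight=shrink_weight,
        )
    else:
        alphas = np.broadcast_to(
            np.asarray(dispersion, dtype=float), (counts.shape[0],)
        ).copy()

    n_genes = counts.shape[0]
    log2fc = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    flags = np.array(["ok"] * n_genes, dtype=object)
    gene_totals = y_all.sum(axis=1)

    for gi in range(n_genes):
        y = y_all[gi]
        if gene_totals[gi] < min_count:
            flags[gi] = "low_count"
            continue
        a = float(alphas[gi])
        bf, llf, okf = _fit_nb_glm(y, Xf, offset, a)
        br, llr, okr = _fit_nb_glm(y, Xr, offset, a)
        if not (okf and okr):
            flags[gi] = "fit_failed"
            continue
        stat = max(2.0 * (llf - llr), 0.0)
        log2fc[gi] = bf[contrast_col] / _LN2
        pval[gi] = chi2.sf(stat, df)

    padj = bh_adjust(pval)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pval,
            "padj": padj,
            "mean_count": y_all.mean(axis=1),
            "flag": flags,
        },
        index=counts.index,
    )
    alt = [l for l in sorted(level_counts.index) if l != (design_full.reference or sorted(level_counts.index)[0])]
    return DEResult(
        table=table,
        contrast=f"{design_full.contrast}:{alt[0]}_vs_{design_full.reference or sorted(level_counts.index)[0]}",
        covariates=tuple(design_full.covariates),
    )


def select_degs(de: DEResult, alpha: float = 0.05, lfc_min: float = 1.0) -> pd.Index:
    """Genes with padj < alpha and |log2fc| >= lfc_min (direction kept)."""
    if alpha <= 0 or lfc_min < 0:
        raise ValueError("thresholds must be positive")
    t = de.table
    mask = (t["padj"] < alpha) & (t["log2fc"].abs() >= lfc_min)
    return t.index[mask.fillna(False)]


def cohort_specific_sets(
    focal: DEResult,
    other: DEResult,
    normal_contrast: DEResult,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.Index:
    """Genes selected in the focal tumor-vs-normal contrast only.

    Returns genes passing both thresholds in ``focal`` while failing at
    least one threshold in ``other`` (the opposite age cohort's
    tumor-vs-normal) and in ``normal_contrast`` (old-vs-young normals).
    Calling with the aging contrast focal gives the aging-cancer-specific
    set; swapping focal/other gives the young-specific set.
    """
    universe = focal.genes
    for de in (other, normal_contrast):
        if not de.genes.equals(universe):
            raise ValueError("DE results are not on a shared gene universe")
    sel_focal = set(select_degs(focal, alpha, lfc_min))
    sel_other = set(select_degs(other, alpha, lfc_min))
    sel_norm = set(select_degs(normal_contrast, alpha, lfc_min))
    keep = [g for g in universe if g in sel_focal and g not in sel_other and g not in sel_norm]
    return pd.Index(keep)
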