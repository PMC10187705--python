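"""Association, survival and prediction-performance statistics.

Thin, uniformly-shaped wrappers over scipy / statsmodels / lifelines for
the standard tests (Pearson chi-square, logistic regression, Kaplan-Meier
log-rank, Cox proportional hazards with Efron ties, Kruskal-Wallis,
Spearman), plus the paired-AUC DeLong test and a jackknife-based paired
C-index comparison implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "PredictionMetrics",
    "chisq_test",
    "logistic_assoc",
    "km_logrank",
    "cox_ph",
    "roc_metrics",
    "delong_test",
    "compare_cindex",
    "kruskal_test",
    "spearman",
]


@dataclass
class ContingencyTable:
    counts: pd.DataFrame  # r x c nonnegative integers with labels

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("contingency counts must be nonnegative")
        if arr.sum() <= 0:
            raise ValueError("contingency table is empty")


@dataclass
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    model: str                 # "univariate" | "multivariate"
    covariates: tuple = ()
    separation: bool = False


@dataclass
class PredictionMetrics:
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    cutpoint: float
    brier: float
    degenerate: bool = False


def chisq_test(table: ContingencyTable | pd.DataFrame | np.ndarray,
               correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence.

    No continuity correction by default (including 2x2 tables); set
    ``correction=True`` for the Yates-corrected 2x2 variant.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else pd.DataFrame(table)
    arr = counts.to_numpy(dtype=float)
    if arr.sum() <= 0:
        raise ValueError("contingency table is empty")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column total: expected counts undefined")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=correction)
    return float(stat), int(df), float(p)


def pearson_residuals(table: ContingencyTable | pd.DataFrame) -> pd.DataFrame:
    """(O - E) / sqrt(E) for every cell."""
    counts = table.counts if isinstance(table, ContingencyTable) else pd.DataFrame(table)
    arr = counts.to_numpy(dtype=float)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    res = (arr - expected) / np.sqrt(expected)
    return pd.DataFrame(res, index=counts.index, columns=counts.columns)


def _encode_covariates(covariates: pd.DataFrame | None, index) -> pd.DataFrame:
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=index)
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            parts.append(pd.get_dummies(s.astype(str), prefix=col, drop_first=True).astype(float))
    return pd.concat(parts, axis=1)


def logistic_assoc(
    y, x, covariates: pd.DataFrame | None = None
) -> AssociationResult:
    """Binomial logistic regression of ``y`` on ``x`` (plus covariates).

    Reports the odds ratio exp(beta_x) with a 95% Wald CI.  Quasi-perfect
    separation is detected from an exploding coefficient or standard
    error and flagged on the result rather than raised.
    """
    y = pd.Series(np.asarray(y)).reset_index(drop=True)
    levels = sorted(pd.unique(y.astype(str)))
    if len(levels) != 2:
        raise ValueError("response must be binary with both levels present")
    yb = (y.astype(str) == levels[1]).astype(float)
    x = pd.Series(np.asarray(x, dtype=float), name="x").reset_index(drop=True)
    X = pd.concat(
        [pd.Series(1.0, index=x.index, name="const"), x,
         _encode_covariates(covariates.reset_index(drop=True) if covariates is not None else None, x.index)],
        axis=1,
    )
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values")
    model = "univariate" if covariates is None or covariates.shape[1] == 0 else "multivariate"
    covs = tuple(covariates.columns) if covariates is not None else ()
    try:
        fit = sm.Logit(yb, X.to_numpy(dtype=float)).fit(
            disp=0, maxiter=200, warn_convergence=False
        )
        beta = fit.params[1]
        se = fit.bse[1]
        p = fit.pvalues[1]
    except Exception:
        return AssociationResult(np.nan, np.nan, np.nan, np.nan, model, covs, separation=True)
    separation = bool(abs(beta) > 15 or se > 50 or not np.isfinite(se))
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    # clip to avoid overflow in exp for quasi-separated fits
    lo, hi, beta_c = (np.clip(v, -700, 700) for v in (lo, hi, beta))
    return AssociationResult(
        float(np.exp(beta_c)), float(np.exp(lo)), float(np.exp(hi)), float(p),
        model, covs, separation=separation,
    )


def km_logrank(time, event, group):
    """Kaplan-Meier curves per group and the log-rank p-value."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise ValueError(
            "no events in any stratum: survival comparison is undefined "
            "(cf. a cohort with no death events)"
        )
    curves = {}
    for g in pd.unique(group):
        kmf = KaplanMeierFitter()
        kmf.fit(time[group == g], event[group == g], label=str(g))
        curves[g] = kmf
    res = multivariate_logrank_test(time, group, event)
    return curves, float(res.p_value)


def cox_ph(
    time, event, x, covariates: pd.DataFrame | None = None
) -> tuple[float, tuple[float, float], float]:
    """Cox proportional-hazards fit (Efron ties); returns (HR, CI, p) for x.

    Strata with zero events are rejected explicitly: a partial-likelihood
    fit there would yield a spurious hazard ratio and Wald p-value.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise ValueError(
            "no events in this stratum: Cox regression would produce a "
            "false hazard-ratio estimate (cf. a cohort with no death events)"
        )
    df = pd.DataFrame({"time": time, "event": event, "x": np.asarray(x, dtype=float)})
    if covariates is not None and covariates.shape[1] > 0:
        enc = _encode_covariates(covariates.reset_index(drop=True), df.index)
        df = pd.concat([df, enc], axis=1)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # lifelines uses Efron ties
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    return np.exp(beta), (np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)), p


# ----------------------------------------------------------------------
# prediction performance

def _auc_mann_whitney(score: np.ndarray, y: np.ndarray) -> float:
    """AUC via the Mann-Whitney identity (ties counted half)."""
    ranks = sps.rankdata(score)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def roc_metrics(score, y, cutpoint_rule: str = "youden") -> PredictionMetrics:
    """AUC, Youden-optimal cut-point, sens/spec/PPV/NPV and Brier score.

    The Brier score treats the (rank-scaled) score as a probability; for
    calibrated probabilities pass them directly as ``score``.
    """
    score = np.asarray(score, dtype=float)
    y01 = np.asarray(y)
    levels = np.unique(y01)
    if levels.size != 2:
        raise ValueError("y must be binary with both classes present")
    yb = (y01 == levels.max()).astype(int) if levels.dtype.kind in "if" else (y01 == sorted(map(str, levels))[1]).astype(int)
    if np.ptp(score) == 0:
        prob = np.full(score.size, yb.mean())
        brier = float(np.mean((prob - yb) ** 2))
        return PredictionMetrics(0.5, np.nan, np.nan, np.nan, np.nan, np.nan, brier, degenerate=True)
    auc = _auc_mann_whitney(score, yb)
    if cutpoint_rule != "youden":
        raise ValueError(f"unknown cut-point rule {cutpoint_rule!r}")
    # candidate cut-points midway between adjacent distinct scores
    uniq = np.unique(score)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1]])
    best, best_j = None, -np.inf
    for c in cands:
        pred = (score > c).astype(int)
        tp = int(((pred == 1) & (yb == 1)).sum())
        fn = int(((pred == 0) & (yb == 1)).sum())
        tn = int(((pred == 0) & (yb == 0)).sum())
        fp = int(((pred == 1) & (yb == 0)).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1
        if j > best_j:
            best_j, best = j, (c, sens, spec, tp, fp, tn, fn)
    c, sens, spec, tp, fp, tn, fn = best
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    # min-max rescale of the score as an implicit probability for Brier
    prob = (score - score.min()) / np.ptp(score)
    brier = float(np.mean((prob - yb) ** 2))
    return PredictionMetrics(auc, sens, spec, ppv, npv, float(c), brier)


def brier_score(prob, y) -> float:
    """Mean squared error of predicted probabilities."""
    prob = np.asarray(prob, dtype=float)
    yb = np.asarray(y, dtype=float)
    return float(np.mean((prob - yb) ** 2))


def harrell_cindex(score, time, event) -> float:
    """Harrell concordance index of a risk score against survival."""
    return float(concordance_index(time, -np.asarray(score, dtype=float), event))


def _delong_components(score: np.ndarray, yb: np.ndarray):
    """DeLong structural components V10 (cases) and V01 (controls)."""
    pos = score[yb == 1]
    neg = score[yb == 0]
    # psi(x, y) = 1 if x > y, 0.5 if tie, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)          # per case
    v01 = psi.mean(axis=0)          # per control
    return v10, v01, psi.mean()


def delong_test(score_a, score_b, y) -> tuple[float, float]:
    """Paired DeLong test of AUC(a) != AUC(b) on identical samples.

    Returns (AUC_a - AUC_b, two-sided p) from the asymptotic normal
    distribution of the paired AUC difference with the DeLong covariance
    estimate.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    yb = np.asarray(y)
    if a.shape != b.shape or a.shape != yb.shape:
        raise ValueError("scores and labels must be paired (same length)")
    yb = (yb == np.max(yb)).astype(int) if yb.dtype.kind in "if" else (yb == sorted(map(str, np.unique(yb)))[1]).astype(int)
    m = int(yb.sum())
    n = int((1 - yb).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    v10a, v01a, auc_a = _delong_components(a, yb)
    v10b, v01b, auc_b = _delong_components(b, yb)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * sps.norm.sf(abs(z)))


def compare_cindex(score_a, score_b, time, event, n_jack: int | None = None) -> tuple[float, float]:
    """Paired comparison of two Harrell C-indices by jackknife.

    Leave-one-out influence values of each C-index give a paired variance
    estimate of the difference, tested against the standard normal — the
    survival analogue of the paired-AUC construction.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (a.shape == b.shape == time.shape == event.shape):
        raise ValueError("inputs must be paired (same length)")
    n = a.size
    ca = harrell_cindex(a, time, event)
    cb = harrell_cindex(b, time, event)
    idx = np.arange(n)
    ja = np.empty(n)
    jb = np.empty(n)
    for i in range(n):
        keep = idx != i
        ja[i] = harrell_cindex(a[keep], time[keep], event[keep])
        jb[i] = harrell_cindex(b[keep], time[keep], event[keep])
    # jackknife pseudo-value covariance of the difference
    d = (ja - jb)
    var = (n - 1) / n * np.sum((d - d.mean()) ** 2)
    delta = ca - cb
    if var <= 0:
        return float(delta), 1.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * sps.norm.sf(abs(z)))


def kruskal_test(values, group) -> float:
    """Kruskal-Wallis rank test across >= 2 groups."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    samples = [values[group == g] for g in pd.unique(group)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    return float(sps.kruskal(*samples).pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
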