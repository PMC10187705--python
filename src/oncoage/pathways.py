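"""Gene-set scoring and age-specific pathway selection.

Over-representation uses the hypergeometric tail; per-sample pathway
activity is summarized either as an agglomerate z-score (mean of the
member genes' z-standardized expression — alternatives: sum or first
principal component) or as a single-sample GSEA normalized enrichment
score (weighted running-sum statistic, linearly rescaled to [0, 1]
across samples per pathway).  Condition-associated pathways are chosen
by per-pathway logistic regression with BH correction, and an
aging-specificity filter removes pathways that are enriched in both age
cohorts in the same direction without differing between them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom, kruskal, mannwhitneyu

from .diffexp import bh_adjust

__all__ = [
    "read_gmt",
    "write_gmt",
    "ora_enrichment",
    "agglomerate_zscore",
    "select_condition_pathways",
    "aging_specificity_filter",
    "ssgsea_nes",
    "compare_nes",
]


# ----------------------------------------------------------------------
# GMT input/output

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        if not genes:
            raise ValueError(f"empty gene set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# over-representation

def ora_enrichment(
    deg_set, collection: dict[str, list[str]], universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``deg_set`` in each set.

    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|set n universe|,
    n=|deg_set|); fold = observed / expected overlap.  Sets with no gene
    in the universe are skipped.
    """
    universe = set(universe)
    degs = set(deg_set) & universe
    if len(set(deg_set)) == 0:
        raise ValueError("empty DEG set")
    if set(deg_set) - universe:
        raise ValueError("DEG set must be a subset of the universe")
    N, n = len(universe), len(degs)
    rows = []
    for name, genes in collection.items():
        K = len(set(genes) & universe)
        if K == 0:
            continue
        k = len(set(genes) & degs)
        p = float(hypergeom.sf(k - 1, N, K, n))
        expected = n * K / N
        fold = k / expected if expected > 0 else np.nan
        rows.append((name, K, k, fold, p))
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "fold", "pvalue"]
    ).set_index("set")
    out["padj"] = bh_adjust(out["pvalue"])
    return out


# ----------------------------------------------------------------------
# per-sample pathway scores

def agglomerate_zscore(
    expr: pd.DataFrame, gene_set, method: str = "mean"
) -> pd.Series:
    """Per-sample agglomerate z-score of a gene set.

    ``expr`` is gene x sample.  Each member gene is z-standardized
    across samples; the per-sample summary is the mean of member
    z-scores (default), their sum, or the first principal component.
    """
    genes = [g for g in gene_set if g in expr.index]
    if not genes:
        raise ValueError("gene set has no overlap with the expression matrix")
    X = expr.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    if method == "mean":
        score = Z.mean(axis=0)
    elif method == "sum":
        score = Z.sum(axis=0)
    elif method == "pc1":
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        pc1 = vt[0]
        if pc1 @ Z.mean(axis=0) < 0:
            pc1 = -pc1
        score = pc1 * np.sqrt(len(genes))
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(score, index=expr.columns, name="agglomerate_z")


def score_matrix(
    expr: pd.DataFrame, collection: dict[str, list[str]], method: str = "mean"
) -> pd.DataFrame:
    """Pathway x sample agglomerate z-score matrix (sets w/o overlap dropped)."""
    rows = {}
    for name, genes in collection.items():
        try:
            rows[name] = agglomerate_zscore(expr, genes, method=method)
        except ValueError:
            continue
    return pd.DataFrame(rows).T


def select_condition_pathways(
    scores: pd.DataFrame, condition, alpha: float = 0.05
) -> pd.DataFrame:
    """Logistic regression of the condition on each pathway score.

    Returns the pathways with BH-adjusted likelihood-ratio p < alpha and
    the sign of the fitted slope as the enrichment direction.
    """
    cond = pd.Series(np.asarray(condition)).astype(str)
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError("condition must be binary with both levels present")
    yb = (cond == levels[1]).astype(float).to_numpy()
    rows = []
    for name, s in scores.iterrows():
        x = s.to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        try:
            fit = sm.Logit(yb, X).fit(disp=0, maxiter=200)
            null = sm.Logit(yb, X[:, :1]).fit(disp=0, maxiter=200)
            from scipy.stats import chi2

            lrt = max(2 * (fit.llf - null.llf), 0.0)
            p = float(chi2.sf(lrt, 1))
            slope = float(fit.params[1])
        except Exception:
            p, slope = np.nan, np.nan
        rows.append((name, slope, np.sign(slope), p))
    out = pd.DataFrame(
        rows, columns=["set", "slope", "direction", "pvalue"]
    ).set_index("set")
    out["padj"] = bh_adjust(out["pvalue"])
    return out[out["padj"] < alpha]


def aging_specificity_filter(
    selected_aging: pd.DataFrame,
    selected_young: pd.DataFrame,
    scores_aging: pd.DataFrame,
    scores_young: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Drop pathways shared with the young cohort in the same direction
    that do not differ between cohorts (Kruskal p >= alpha)."""
    keep = []
    for name in selected_aging.index:
        if name in selected_young.index and (
            selected_aging.loc[name, "direction"]
            == selected_young.loc[name, "direction"]
        ):
            a = scores_aging.loc[name].to_numpy(dtype=float)
            y = scores_young.loc[name].to_numpy(dtype=float)
            p = float(kruskal(a, y).pvalue)
            if p >= alpha:
                continue
        keep.append(name)
    return selected_aging.loc[keep]


# ----------------------------------------------------------------------
# single-sample GSEA

def _ssgsea_sample(expr_vals: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Weighted running-sum enrichment score for one sample.

    Genes are ranked by decreasing expression; the statistic is the sum
    over ranks of the difference between the weighted in-set cumulative
    distribution (weights |rank value|^weight) and the uniform
    out-of-set cumulative distribution.
    """
    order = np.argsort(-expr_vals, kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    n = expr_vals.size
    # rank weights: descending rank positions n..1 raised to `weight`
    rank_vals = np.abs(n - np.arange(n, dtype=float))  # n, n-1, ..., 1
    hits = in_set[order]
    w = rank_vals**weight * hits
    denom_in = w.sum()
    n_out = n - in_set.sum()
    if denom_in == 0 or n_out == 0:
        raise ValueError("gene set covers none or all of the genes")
    cdf_in = np.cumsum(w) / denom_in
    cdf_out = np.cumsum(~hits.astype(bool)) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_nes(
    expr: pd.DataFrame, gene_set, weight: float = 0.25, rescale: bool = True
) -> pd.Series:
    """Single-sample GSEA score per sample, rescaled to [0, 1].

    ``expr`` is gene x sample.  At ``weight=0`` the statistic is purely
    rank-based and hence invariant to any strictly monotone transform of
    a sample's expression values.  ``rescale=False`` returns the raw
    running-sum scores.
    """
    members = set(gene_set)
    in_set = np.array([g in members for g in expr.index])
    if in_set.sum() < 2:
        raise ValueError("gene set must overlap the matrix in >= 2 genes")
    X = expr.to_numpy(dtype=float)
    raw = np.array(
        [_ssgsea_sample(X[:, j], in_set, weight) for j in range(X.shape[1])]
    )
    if rescale:
        span = np.ptp(raw)
        raw = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    return pd.Series(raw, index=expr.columns, name="ssgsea_nes")


def compare_nes(nes: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Rank-test each pathway's NES across sample groups (+ BH).

    Two groups use Mann-Whitney, more use Kruskal-Wallis.  Groups with
    fewer than 3 samples flag the pathway ``small_group``.
    """
    groups = groups.loc[nes.columns]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    small = any((groups == g).sum() < 3 for g in levels)
    rows = []
    for name, s in nes.iterrows():
        samples = [s[groups.index[groups == g]].to_numpy(dtype=float) for g in levels]
        try:
            if len(levels) == 2:
                p = float(mannwhitneyu(samples[0], samples[1]).pvalue)
            else:
                p = float(kruskal(*samples).pvalue)
        except ValueError:
            p = np.nan
        rows.append((name, p, "small_group" if small else "ok"))
    out = pd.DataFrame(rows, columns=["set", "pvalue", "flag"]).set_index("set")
    out["padj"] = bh_adjust(out["pvalue"])
    return out
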