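"""Cluster-by-parameter aggressiveness hierarchy.

For each clinical parameter, a level x cluster contingency table is
tested with Pearson chi-square (no continuity correction).  For the
significant parameters, a cluster is called enriched in the aggressive
level when its standardized Pearson residual for that level exceeds a
threshold (default 2), and enriched in the non-aggressive level
symmetrically.  Each cluster's aggressiveness ratio is
(n_aggressive - n_non_aggressive) / n_significant_parameters, bounded in
[-1, 1], and clusters are ranked by descending ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import chisq_test, pearson_residuals

__all__ = [
    "ParameterTable",
    "ClusterParameterEnrichment",
    "HierarchyResult",
    "cluster_parameter_tables",
    "enrichment_directions",
    "aggressiveness_ratio",
    "rank_clusters",
    "run_hierarchy",
]


@dataclass
class ParameterTable:
    """One parameter's level x cluster counts and chi-square result."""

    parameter: str
    counts: pd.DataFrame        # levels x clusters
    aggressive_level: str
    non_aggressive_level: str
    statistic: float
    df: int
    pvalue: float


@dataclass
class ClusterParameterEnrichment:
    """Per (cluster, parameter) enrichment calls for significant params."""

    calls: pd.DataFrame  # parameter x cluster in {aggressive, non-aggressive, none}
    residuals: dict      # parameter -> residual DataFrame
    significant: list    # parameters with p < alpha


@dataclass
class HierarchyResult:
    summary: pd.DataFrame  # per cluster: n_aggressive, n_non_aggressive, ratio
    ranking: list
    tied: bool = False


def cluster_parameter_tables(
    clinical: pd.DataFrame,
    clusters: pd.Series,
    parameter_defs: list[tuple],
) -> list[ParameterTable]:
    """Build one contingency table per parameter and chi-square test it.

    ``parameter_defs`` holds (name, column, aggressive_level,
    non_aggressive_level) tuples; columns are used as-is (dichotomize
    continuous parameters beforehand).  Clusters with no samples raise.
    """
    clusters = clusters.loc[clinical.index]
    if isinstance(clusters.dtype, pd.CategoricalDtype):
        cluster_levels = list(clusters.cat.categories)
    else:
        cluster_levels = sorted(pd.unique(clusters))
    out = []
    for name, column, agg_level, non_level in parameter_defs:
        tab = pd.crosstab(clinical[column].astype(str), clusters)
        tab = tab.reindex(columns=cluster_levels, fill_value=0)
        if (tab.sum(axis=0) == 0).any():
            raise ValueError("a cluster has no samples for parameter " + name)
        stat, df, p = chisq_test(tab)
        out.append(
            ParameterTable(
                parameter=name,
                counts=tab,
                aggressive_level=str(agg_level),
                non_aggressive_level=str(non_level),
                statistic=stat,
                df=df,
                pvalue=p,
            )
        )
    return out


def enrichment_directions(
    tables: list[ParameterTable],
    residual_thr: float = 2.0,
    alpha: float = 0.05,
) -> ClusterParameterEnrichment:
    """Aggressive / non-aggressive enrichment calls per cluster.

    Only parameters with chi-square p < alpha receive calls.  A cluster
    is called "aggressive" for a parameter when its Pearson residual in
    the aggressive level strictly exceeds ``residual_thr``,
    "non-aggressive" when the non-aggressive level's residual does, and
    "none" otherwise (including a residual exactly at the threshold).
    """
    clusters = tables[0].counts.columns
    calls = pd.DataFrame(
        "none", index=[t.parameter for t in tables], columns=clusters
    )
    residuals = {}
    significant = []
    for t in tables:
        res = pearson_residuals(t.counts)
        residuals[t.parameter] = res
        if t.pvalue >= alpha:
            continue
        significant.append(t.parameter)
        for cl in clusters:
            if t.aggressive_level in res.index and res.loc[t.aggressive_level, cl] > residual_thr:
                calls.loc[t.parameter, cl] = "aggressive"
            elif t.non_aggressive_level in res.index and res.loc[t.non_aggressive_level, cl] > residual_thr:
                calls.loc[t.parameter, cl] = "non-aggressive"
    return ClusterParameterEnrichment(calls=calls, residuals=residuals, significant=significant)


def aggressiveness_ratio(n_agg: int, n_non: int, n_params: int) -> float:
    """(n_aggressive - n_non_aggressive) / n_params, 2-decimal rounded."""
    if n_params <= 0:
        raise ValueError("n_params must be positive")
    if n_agg + n_non > n_params:
        raise ValueError("more calls than significant parameters")
    return round((n_agg - n_non) / n_params, 2)


def rank_clusters(result: HierarchyResult) -> list:
    """Cluster labels by descending ratio; ties broken by n_aggressive,
    then label alphabetically."""
    df = result.summary.sort_index()  # alphabetical base order for ties
    order = df.sort_values("n_aggressive", ascending=False, kind="mergesort")
    order = order.sort_values("ratio", ascending=False, kind="mergesort")
    return list(order.index)


def summarize_hierarchy(enrich: ClusterParameterEnrichment) -> HierarchyResult:
    """Aggregate enrichment calls into per-cluster ratios and a ranking.

    With no significant parameter at all, every ratio is 0 by convention
    (no enrichment evidence in either direction) and the ranking is a tie.
    """
    n_params = len(enrich.significant)
    sig_calls = enrich.calls.loc[enrich.significant]
    rows = {}
    for cl in enrich.calls.columns:
        n_agg = int((sig_calls[cl] == "aggressive").sum())
        n_non = int((sig_calls[cl] == "non-aggressive").sum())
        rows[cl] = {
            "n_aggressive": n_agg,
            "n_non_aggressive": n_non,
            "ratio": (
                aggressiveness_ratio(n_agg, n_non, n_params) if n_params else 0.0
            ),
        }
    summary = pd.DataFrame(rows).T
    summary[["n_aggressive", "n_non_aggressive"]] = summary[
        ["n_aggressive", "n_non_aggressive"]
    ].astype(int)
    result = HierarchyResult(summary=summary, ranking=[])
    result.tied = bool(summary["ratio"].duplicated().any())
    result.ranking = rank_clusters(result)
    return result


def run_hierarchy(
    clinical: pd.DataFrame,
    clusters: pd.Series,
    parameter_defs: list[tuple],
    residual_thr: float = 2.0,
    alpha: float = 0.05,
) -> tuple[list[ParameterTable], ClusterParameterEnrichment, HierarchyResult]:
    tables = cluster_parameter_tables(clinical, clusters, parameter_defs)
    enrich = enrichment_directions(tables, residual_thr=residual_thr, alpha=alpha)
    return tables, enrich, summarize_hierarchy(enrich)
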