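"""Gene-level copy-number alteration calling and downstream screens.

Calls are thresholded on the segment-mean (log2-ratio-like) scale: a
shallow gain is CNV > 0.3, a shallow loss CNV < -0.3, both strict;
values exactly at a threshold are neutral.  A deep-alteration screen is
the same caller at |CNV| > 1.  Per-group alteration frequencies above 2%
(strict) are flagged as relevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import DEResult, bh_adjust
from .stats import chisq_test, spearman

__all__ = [
    "AlterationCallMatrix",
    "call_alterations",
    "alteration_frequency",
    "differential_alteration",
    "cnv_expression_link",
]

GAIN, NEUTRAL, LOSS = 1, 0, -1


@dataclass
class AlterationCallMatrix:
    """gene x sample calls in {-1: loss, 0: neutral, +1: gain}."""

    calls: pd.DataFrame
    gain_thr: float
    loss_thr: float


def call_alterations(
    cnv: pd.DataFrame, gain_thr: float = 0.3, loss_thr: float = -0.3
) -> AlterationCallMatrix:
    if not (gain_thr > 0 > loss_thr):
        raise ValueError("need gain_thr > 0 > loss_thr")
    arr = cnv.to_numpy(dtype=float)
    calls = np.where(arr > gain_thr, GAIN, np.where(arr < loss_thr, LOSS, NEUTRAL))
    return AlterationCallMatrix(
        calls=pd.DataFrame(calls, index=cnv.index, columns=cnv.columns),
        gain_thr=gain_thr,
        loss_thr=loss_thr,
    )


def alteration_frequency(
    calls: AlterationCallMatrix, groups: pd.Series, relevance_thr: float = 0.02
) -> pd.DataFrame:
    """Per-gene, per-group gain/loss frequencies.

    Returns a long table (gene, group, n_gain, n_loss, n_total,
    freq_gain, freq_loss, retained) where ``retained`` marks a gain or
    loss frequency strictly above ``relevance_thr``.
    """
    groups = groups.loc[calls.calls.columns]
    rows = []
    for g in pd.unique(groups):
        cols = groups.index[groups == g]
        if len(cols) == 0:
            raise ValueError(f"empty group {g!r}")
        sub = calls.calls[cols].to_numpy()
        n_gain = (sub == GAIN).sum(axis=1)
        n_loss = (sub == LOSS).sum(axis=1)
        n_total = sub.shape[1]
        rows.append(
            pd.DataFrame(
                {
                    "gene": calls.calls.index,
                    "group": g,
                    "n_gain": n_gain,
                    "n_loss": n_loss,
                    "n_total": n_total,
                    "freq_gain": n_gain / n_total,
                    "freq_loss": n_loss / n_total,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["retained"] = (out["freq_gain"] > relevance_thr) | (
        out["freq_loss"] > relevance_thr
    )
    return out


def differential_alteration(
    calls: AlterationCallMatrix, groups: pd.Series, group_a, group_b
) -> pd.DataFrame:
    """Per-gene 2x2 chi-square of altered-vs-not between two groups.

    Genes with a degenerate margin (altered in no sample, or in all) are
    skipped with flag ``degenerate``; the rest get BH-adjusted p-values.
    """
    groups = groups.loc[calls.calls.columns]
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both groups must be non-empty")
    altered = (calls.calls != NEUTRAL).astype(int)
    rows = []
    for gene in calls.calls.index:
        a_alt = int(altered.loc[gene, cols_a].sum())
        b_alt = int(altered.loc[gene, cols_b].sum())
        table = np.array(
            [[a_alt, len(cols_a) - a_alt], [b_alt, len(cols_b) - b_alt]]
        )
        if (table.sum(axis=0) == 0).any():
            rows.append((gene, np.nan, "degenerate"))
            continue
        _, _, p = chisq_test(table)
        rows.append((gene, p, "ok"))
    out = pd.DataFrame(rows, columns=["gene", "pvalue", "flag"]).set_index("gene")
    out["padj"] = bh_adjust(out["pvalue"])
    return out


def cnv_expression_link(
    cnv: pd.DataFrame,
    expr: pd.DataFrame,
    de: DEResult,
    freq: pd.DataFrame,
    group: str,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    freq_thr: float = 0.02,
) -> pd.Index:
    """Genes whose expression change is linked to their copy number.

    Gains: Spearman rho(CNV, expression) > 0 with BH-adjusted p < alpha,
    gain frequency > ``freq_thr`` in ``group``, and DE log2fc > lfc_min
    with padj < alpha.  Losses mirror the rule (positive rho, loss
    frequency, log2fc < -lfc_min).
    """
    if not cnv.index.equals(expr.index) or not cnv.columns.equals(expr.columns):
        raise ValueError("cnv and expression matrices are misaligned")
    sub = freq[freq["group"] == group].set_index("gene")
    rhos, ps = {}, {}
    for gene in cnv.index:
        rho, p = spearman(cnv.loc[gene], expr.loc[gene])
        rhos[gene], ps[gene] = rho, p
    padj = pd.Series(
        bh_adjust(pd.Series(ps).to_numpy()), index=pd.Series(ps).index
    )
    rho_s = pd.Series(rhos)
    t = de.table
    keep = []
    for gene in cnv.index:
        corr_ok = rho_s[gene] > 0 and padj[gene] < alpha
        if not corr_ok or gene not in t.index:
            continue
        lfc = t.loc[gene, "log2fc"]
        de_ok = pd.notna(t.loc[gene, "padj"]) and t.loc[gene, "padj"] < alpha
        gain_ok = sub.loc[gene, "freq_gain"] > freq_thr and de_ok and lfc > lfc_min
        loss_ok = sub.loc[gene, "freq_loss"] > freq_thr and de_ok and lfc < -lfc_min
        if gain_ok or loss_ok:
            keep.append(gene)
    return pd.Index(keep)
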