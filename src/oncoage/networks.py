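"""Correlation-filtered regulatory networks and loop detection.

Candidate regulator->target edges (transcription factors, miRNAs,
lncRNAs, proteins) are filtered by the Spearman correlation of the two
endpoints' expression, keeping |rho| strictly above a threshold (0.5 for
tumor networks; 0.3 is conventional for normal-tissue networks).
Regulatory loops are triads of two regulators of different classes plus
one target gene where all three pairwise candidate edges survive the
filter.  miRNA edges carry an interaction-site annotation used to call
the miRNA an activator (promoter site, positive correlation) or
inhibitor (3'UTR/CDS/5'UTR site, negative correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import spearman

__all__ = [
    "CandidateEdge",
    "RegulatoryLoop",
    "correlation_filter",
    "find_loops",
    "classify_mirna_mode",
    "loop_difference",
]

REGULATOR_CLASSES = ("TF", "miRNA", "lncRNA", "protein")
MIRNA_SITES = ("promoter", "5UTR", "CDS", "3UTR", "none")

#: loop kind -> the (unordered) pair of regulator classes involved
LOOP_KINDS = {
    frozenset(("TF", "miRNA")): "TF/miRNA/DEG",
    frozenset(("TF", "lncRNA")): "TF/lncRNA/DEG",
    frozenset(("miRNA", "lncRNA")): "miRNA/lncRNA/DEG",
}


@dataclass(frozen=True)
class CandidateEdge:
    regulator: str
    regulator_class: str
    target: str
    site: str = "none"  # miRNA edges must carry a site annotation

    def __post_init__(self):
        if self.regulator_class not in REGULATOR_CLASSES:
            raise ValueError(f"unknown regulator class {self.regulator_class!r}")
        if self.site not in MIRNA_SITES:
            raise ValueError(f"unknown site class {self.site!r}")
        if self.regulator_class == "miRNA" and self.site == "none":
            raise ValueError("miRNA edges must carry a site class")


@dataclass(frozen=True)
class RegulatoryLoop:
    kind: str
    regulator_a: str
    regulator_b: str
    target: str
    rho_a_target: float
    rho_b_target: float
    rho_a_b: float


def correlation_filter(
    expr: pd.DataFrame, edges: list[CandidateEdge], threshold: float = 0.5
) -> pd.DataFrame:
    """Spearman-correlate each edge's endpoints; keep |rho| > threshold.

    ``expr`` is feature x sample and must quantify both endpoints; edges
    with an unquantified endpoint are dropped with a warning.  Returns a
    table (regulator, regulator_class, target, site, rho).
    """
    rows = []
    dropped = 0
    for e in edges:
        if e.regulator not in expr.index or e.target not in expr.index:
            dropped += 1
            continue
        rho, _ = spearman(expr.loc[e.regulator], expr.loc[e.target])
        if abs(rho) > threshold:
            rows.append((e.regulator, e.regulator_class, e.target, e.site, rho))
    if dropped:
        warnings.warn(f"dropped {dropped} edges with unquantified endpoints")
    return pd.DataFrame(
        rows, columns=["regulator", "regulator_class", "target", "site", "rho"]
    )


def find_loops(filtered_edges: pd.DataFrame, deg_set) -> list[RegulatoryLoop]:
    """Enumerate regulator-pair loops onto targets in ``deg_set``.

    A loop is (regulator A, regulator B, target gene) where A->target,
    B->target and a regulator-regulator edge (either direction) all
    survived the correlation filter, A and B belong to the class pair of
    one loop kind, and target is in ``deg_set``.  Deduplicated; the pair
    ordering within a loop is canonical (sorted by class then id).
    """
    deg_set = set(deg_set)
    if filtered_edges.empty:
        return []
    cls = {}
    for _, r in filtered_edges.iterrows():
        cls[r["regulator"]] = r["regulator_class"]
    # edges regulator -> target with rho, and regulator<->regulator links
    reg_target: dict[tuple, float] = {}
    reg_reg: dict[frozenset, float] = {}
    for _, r in filtered_edges.iterrows():
        key = (r["regulator"], r["target"])
        reg_target[key] = r["rho"]
        if r["target"] in cls:  # target is itself a regulator
            reg_reg[frozenset((r["regulator"], r["target"]))] = r["rho"]
    by_target: dict[str, list] = {}
    for (reg, tgt), rho in reg_target.items():
        by_target.setdefault(tgt, []).append((reg, rho))
    loops = {}
    for tgt, regs in by_target.items():
        if tgt not in deg_set:
            continue
        for i in range(len(regs)):
            for j in range(i + 1, len(regs)):
                (ra, rho_a), (rb, rho_b) = regs[i], regs[j]
                kind = LOOP_KINDS.get(frozenset((cls.get(ra), cls.get(rb))))
                if kind is None:
                    continue
                link = reg_reg.get(frozenset((ra, rb)))
                if link is None:
                    continue
                a, b = sorted([ra, rb], key=lambda r: (cls[r], r))
                rho_at = reg_target[(a, tgt)]
                rho_bt = reg_target[(b, tgt)]
                loops[(kind, a, b, tgt)] = RegulatoryLoop(
                    kind, a, b, tgt, rho_at, rho_bt, link
                )
    return [loops[k] for k in sorted(loops)]


def loop_difference(
    loops_a: list[RegulatoryLoop], loops_b: list[RegulatoryLoop]
) -> list[RegulatoryLoop]:
    """Loops present in ``loops_a`` but not in ``loops_b`` (by identity
    of kind, regulators and target) — e.g. loops unique to one cohort."""
    seen = {(l.kind, l.regulator_a, l.regulator_b, l.target) for l in loops_b}
    return [
        l
        for l in loops_a
        if (l.kind, l.regulator_a, l.regulator_b, l.target) not in seen
    ]


def classify_mirna_mode(site: str, rho: float) -> str:
    """Activator / inhibitor / unclassified call for one miRNA edge.

    Promoter interaction with positive correlation -> activator;
    3'UTR/CDS/5'UTR interaction with negative correlation -> inhibitor;
    anything else is unclassified.
    """
    if site not in MIRNA_SITES:
        raise ValueError(f"unknown site class {site!r}")
    if site == "promoter" and rho > 0:
        return "activator"
    if site in ("3UTR", "CDS", "5UTR") and rho < 0:
        return "inhibitor"
    return "unclassified"
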