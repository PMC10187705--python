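"""Four-step aging-dependent aggressiveness signature selection.

Starting from the age-cohort-specific differentially expressed genes
(step 1), the pipeline keeps genes whose expression is associated
(gender/race-adjusted) with at least two of four aggressiveness
parameters — lymph-node metastasis, extrathyroidal extension, tumor
size and aggressive histological type (step 2); whose association signs
all agree with the cancer fold-change direction (step 3); whose
associations vanish once age joins the adjustment — the defining
aging-dependence criterion (step 4); and which retain at least one
significant association with a wider aggressiveness/outcome parameter
set inside the aging tumor cohort itself (internal validation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .diffexp import (
    DEResult,
    DesignSpec,
    bh_adjust,
    cohort_specific_sets,
    nb_glm_lrt,
    size_factors,
)
from .stats import cox_ph, logistic_assoc

__all__ = [
    "ParameterDefinition",
    "AssociationMatrix",
    "SignaturePanel",
    "SELECTION_PARAMETERS",
    "VALIDATION_PARAMETERS",
    "compute_association_matrix",
    "step2_min_parameter_hits",
    "step3_directional_concordance",
    "step4_aging_dependence",
    "internal_validation",
    "run_signature_pipeline",
]


@dataclass(frozen=True)
class ParameterDefinition:
    """A clinical parameter recoded to a two-level aggressiveness factor.

    ``kind``: "binary" groups ``aggressive_levels`` of a categorical
    column against the rest; "threshold" splits a continuous column at
    ``threshold`` (aggressive side per ``aggressive_side``); "mean"
    splits at the cohort mean.
    """

    name: str
    column: str
    kind: str = "binary"
    aggressive_levels: tuple = ()
    threshold: float | None = None
    aggressive_side: str = "high"

    def encode(self, clinical: pd.DataFrame) -> pd.Series:
        if self.column not in clinical.columns:
            raise KeyError(f"missing parameter column {self.column!r}")
        col = clinical[self.column]
        if self.kind == "binary":
            agg = col.astype(str).isin([str(l) for l in self.aggressive_levels])
        elif self.kind in ("threshold", "mean"):
            cut = float(col.mean()) if self.kind == "mean" else float(self.threshold)
            agg = col.astype(float) >= cut
            if self.aggressive_side == "low":
                agg = ~agg
        else:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        return pd.Series(
            np.where(agg, "aggressive", "non_aggressive"),
            index=clinical.index,
            name=self.name,
        )


#: The four named aggressiveness parameters of the selection steps.
SELECTION_PARAMETERS = (
    ParameterDefinition("LNM", "LNM", "binary", ("N1",)),
    ParameterDefinition("ETE", "ETE", "binary", ("present", "gross")),
    ParameterDefinition("tumor_size_1cm", "tumor_size_cm", "threshold", threshold=1.0),
    ParameterDefinition("histotype", "histotype", "binary", ("CPTC", "TPTC")),
)

#: Internal-validation parameters (aging tumor cohort): clinical and
#: molecular aggressiveness markers plus the four survival endpoints.
VALIDATION_PARAMETERS = (
    ParameterDefinition("LNM", "LNM", "binary", ("N1",)),
    ParameterDefinition("ETE_present", "ETE", "binary", ("present", "gross")),
    ParameterDefinition("ETE_gross", "ETE", "binary", ("gross",)),
    ParameterDefinition("hist_CT_vs_F", "histotype", "binary", ("CPTC", "TPTC")),
    ParameterDefinition("hist_T_vs_FC", "histotype", "binary", ("TPTC",)),
    ParameterDefinition("size_1cm", "tumor_size_cm", "threshold", threshold=1.0),
    ParameterDefinition("size_2cm", "tumor_size_cm", "threshold", threshold=2.0),
    ParameterDefinition(
        "differentiation", "differentiation_score", "mean", aggressive_side="low"
    ),
    ParameterDefinition("BRAF", "BRAF", "binary", ("MUT",)),
    ParameterDefinition("TERT", "TERT", "binary", ("MUT",)),
)

SURVIVAL_ENDPOINTS = ("DFS", "PFI", "OS", "DSS")


@dataclass
class AssociationMatrix:
    """Gene x parameter association summaries for one adjustment mode.

    ``t`` is the transformed adjusted p-value,
    sign(log2fc) * |log2(padj)|; companions hold raw padj and log2fc.
    """

    t: pd.DataFrame
    padj: pd.DataFrame
    log2fc: pd.DataFrame
    covariates: tuple = ()

    @property
    def parameters(self) -> list:
        return list(self.t.columns)


@dataclass
class SignaturePanel:
    """Final gene list with complete per-step provenance."""

    genes: list
    provenance: pd.DataFrame   # per step-1 gene: survived_step1..4, validated
    validation_hits: pd.DataFrame  # gene x validation parameter (bool)
    step_counts: dict = field(default_factory=dict)
    mode: str = "aging"


def compute_association_matrix(
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    genes,
    parameters=SELECTION_PARAMETERS,
    covariates: tuple = ("gender", "race"),
    min_count: int = 10,
) -> AssociationMatrix:
    """NB-GLM LRT of each parameter contrast over the candidate genes.

    BH adjustment is across genes within each parameter.
    """
    genes = pd.Index(genes)
    sub = counts.loc[genes]
    sf = size_factors(counts)  # from the full matrix, not the candidates
    t, padj, lfc = {}, {}, {}
    for p in parameters:
        enc = p.encode(clinical)
        clin = clinical.copy()
        clin["_param"] = enc
        design = DesignSpec("_param", covariates=covariates, reference="non_aggressive")
        # dispersion from cells homogeneous in parameter AND age group, so
        # age-driven expression structure is not mistaken for noise
        if "age_group" in clinical.columns:
            disp_groups = enc.astype(str) + "/" + clinical["age_group"].astype(str)
        else:
            disp_groups = enc.astype(str)
        de = nb_glm_lrt(
            sub, clin, design, min_count=min_count, dispersion_groups=disp_groups,
            precomputed_size_factors=sf,
        )
        padj[p.name] = de["padj"]
        lfc[p.name] = de["log2fc"]
        with np.errstate(divide="ignore"):
            t[p.name] = np.sign(de["log2fc"]) * np.abs(np.log2(de["padj"]))
    return AssociationMatrix(
        t=pd.DataFrame(t),
        padj=pd.DataFrame(padj),
        log2fc=pd.DataFrame(lfc),
        covariates=tuple(covariates),
    )


def step2_min_parameter_hits(
    assoc: AssociationMatrix,
    parameters=None,
    k_min: int = 2,
    alpha: float = 0.05,
) -> pd.Index:
    """Genes significant for at least ``k_min`` of the named parameters."""
    names = [p.name for p in (parameters or SELECTION_PARAMETERS)]
    missing = [n for n in names if n not in assoc.padj.columns]
    if missing:
        raise KeyError(f"association matrix lacks parameters {missing}")
    if not 1 <= k_min <= len(names):
        raise ValueError("k_min must be between 1 and the parameter count")
    hits = (assoc.padj[names] < alpha).sum(axis=1)
    return assoc.padj.index[hits >= k_min]


def cluster_association_profiles(assoc: AssociationMatrix, genes) -> np.ndarray:
    """Average-linkage/Euclidean clustering of transformed-padj rows.

    Reporting aid only: the concordance filter below does not depend on
    the dendrogram.
    """
    X = assoc.t.loc[pd.Index(genes)].fillna(0.0).to_numpy(dtype=float)
    return linkage(X, method="average", metric="euclidean")


def step3_directional_concordance(
    assoc: AssociationMatrix,
    cancer_de: DEResult,
    genes=None,
    alpha: float = 0.05,
) -> pd.Index:
    """Keep genes whose significant association signs all match the
    cancer fold-change sign.

    Genes upregulated in cancer must associate positively with every
    significant aggressive parameter, downregulated genes negatively.
    A gene with no significant association at this stage is dropped
    (vacuous concordance is not granted).
    """
    idx = pd.Index(genes) if genes is not None else assoc.padj.index
    keep = []
    for g in idx:
        if g not in cancer_de.table.index:
            continue
        cancer_sign = np.sign(cancer_de.table.loc[g, "log2fc"])
        sig = assoc.padj.loc[g] < alpha
        if not sig.any() or cancer_sign == 0:
            continue
        signs = np.sign(assoc.log2fc.loc[g][sig])
        if (signs == cancer_sign).all():
            keep.append(g)
    return pd.Index(keep)


def step4_aging_dependence(
    padj_gr: pd.DataFrame,
    padj_agr: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "nonsig",
) -> pd.Index:
    """Genes whose association needs age absent from the adjustment.

    A gene qualifies on a parameter when the gender/race-adjusted padj
    is < alpha while the age/gender/race-adjusted padj is > alpha
    (``mode="nonsig"``) or merely larger than the gender/race padj
    (``mode="weaker"``); one qualifying parameter suffices.
    """
    if not padj_gr.index.equals(padj_agr.index) or list(padj_gr.columns) != list(
        padj_agr.columns
    ):
        raise ValueError("adjustment-mode matrices are misaligned")
    if mode == "nonsig":
        qual = (padj_gr < alpha) & (padj_agr > alpha)
    elif mode == "weaker":
        qual = (padj_gr < alpha) & ((padj_agr > alpha) | (padj_agr > padj_gr))
    else:
        raise ValueError("mode must be 'nonsig' or 'weaker'")
    return padj_gr.index[qual.any(axis=1)]


def _log2_normalized(counts: pd.DataFrame, genes) -> pd.DataFrame:
    # size factors from the full matrix, expression for the panel genes
    sf = size_factors(counts)
    return np.log2(counts.loc[pd.Index(genes)] / sf[None, :] + 1.0)


def internal_validation(
    panel_genes,
    counts: pd.DataFrame,
    clinical: pd.DataFrame,
    survival: pd.DataFrame,
    parameters=VALIDATION_PARAMETERS,
    endpoints=SURVIVAL_ENDPOINTS,
    covariates: tuple = ("gender", "race"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene association screen inside the aging tumor cohort.

    Binary/dichotomized parameters: logistic regression of the parameter
    on the gene's standardized log2 expression, covariate-adjusted.
    Survival endpoints: Cox proportional-hazards on the same expression.
    Endpoints with zero events are skipped with a warning (a stratum
    with no events admits no hazard model).  BH is applied across genes
    within each parameter; the returned boolean frame marks padj < alpha.
    """
    genes = pd.Index(panel_genes)
    expr = _log2_normalized(counts, genes)
    z = expr.sub(expr.mean(axis=1), axis=0)
    sd = expr.std(axis=1, ddof=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    cov_df = clinical[list(covariates)]
    pcols = {}
    for p in parameters:
        enc = p.encode(clinical)
        if enc.nunique() < 2:
            warnings.warn(f"parameter {p.name} has one level in this cohort; skipped")
            continue
        yb = (enc == "aggressive").astype(int)
        pv = []
        for g in genes:
            res = logistic_assoc(yb.to_numpy(), z.loc[g].to_numpy(), covariates=cov_df)
            pv.append(np.nan if res.separation else res.pvalue)
        pcols[p.name] = bh_adjust(np.array(pv))
    for ep in endpoints:
        time = survival[f"{ep}_time"]
        event = survival[f"{ep}_event"]
        if int(event.sum()) == 0:
            warnings.warn(
                f"endpoint {ep} has zero events in this cohort; skipped "
                "(no-event stratum)"
            )
            continue
        pv = []
        for g in genes:
            try:
                _, _, p_val = cox_ph(
                    time.to_numpy(), event.to_numpy(), z.loc[g].to_numpy(),
                    covariates=cov_df,
                )
            except Exception:
                p_val = np.nan
            pv.append(p_val)
        pcols[ep] = bh_adjust(np.array(pv))
    padj = pd.DataFrame(pcols, index=genes)
    return padj < alpha


@dataclass(frozen=True)
class SignatureConfig:
    alpha: float = 0.05
    lfc_min: float = 1.0
    k_min: int = 2
    aging_dependence_mode: str = "nonsig"
    min_count: int = 10


def run_signature_pipeline(
    cohort,
    config: SignatureConfig | None = None,
    mode: str = "aging",
) -> SignaturePanel:
    """Chain step 1 through internal validation on one cohort.

    ``mode="aging"`` selects the aging-cancer-specific aggressiveness
    panel; ``mode="young"`` runs the symmetric young-cohort variant
    (cohort-specific DE in the young contrast, validation within young
    tumors).
    """
    cfg = config or SignatureConfig()
    if mode not in ("aging", "young"):
        raise ValueError("mode must be 'aging' or 'young'")
    clinical = cohort.clinical
    for ag in ("aging", "young"):
        for ts in ("tumor", "normal"):
            if ((clinical["age_group"] == ag) & (clinical["tissue"] == ts)).sum() < 2:
                raise ValueError(f"cohort lacks {ag} {ts} samples")

    def _contrast(mask, contrast_col, reference):
        sub_clin = clinical[mask]
        sub_counts = cohort.counts.loc[:, sub_clin.index]
        design = DesignSpec(contrast_col, covariates=("gender", "race"), reference=reference)
        return nb_glm_lrt(sub_counts, sub_clin, design, min_count=cfg.min_count)

    aging_de = _contrast(clinical["age_group"] == "aging", "tissue", "normal")
    young_de = _contrast(clinical["age_group"] == "young", "tissue", "normal")
    normal_de = _contrast(clinical["tissue"] == "normal", "age_group", "young")

    focal_de, other_de = (
        (aging_de, young_de) if mode == "aging" else (young_de, aging_de)
    )
    step1 = cohort_specific_sets(
        focal_de, other_de, normal_de, alpha=cfg.alpha, lfc_min=cfg.lfc_min
    )

    tumors = clinical["tissue"] == "tumor"
    tumor_clin = clinical[tumors]
    tumor_counts = cohort.counts.loc[:, tumor_clin.index]
    if len(step1):
        assoc_gr = compute_association_matrix(
            tumor_counts, tumor_clin, step1, covariates=("gender", "race"),
            min_count=cfg.min_count,
        )
        assoc_agr = compute_association_matrix(
            tumor_counts, tumor_clin, step1,
            covariates=("age_group", "gender", "race"), min_count=cfg.min_count,
        )
        step2 = step2_min_parameter_hits(assoc_gr, k_min=cfg.k_min, alpha=cfg.alpha)
        step3 = step3_directional_concordance(
            assoc_gr, focal_de, genes=step2, alpha=cfg.alpha
        )
        step4 = step4_aging_dependence(
            assoc_gr.padj.loc[step3],
            assoc_agr.padj.loc[step3],
            alpha=cfg.alpha,
            mode=cfg.aging_dependence_mode,
        )
    else:
        step2 = step3 = step4 = pd.Index([])

    own_age = "aging" if mode == "aging" else "young"
    own_tumors = tumors & (clinical["age_group"] == own_age)
    if len(step4):
        hits = internal_validation(
            step4,
            cohort.counts.loc[:, clinical[own_tumors].index],
            clinical[own_tumors],
            cohort.survival.loc[clinical[own_tumors].index],
            alpha=cfg.alpha,
        )
        validated = hits.index[hits.any(axis=1)]
    else:
        hits = pd.DataFrame()
        validated = pd.Index([])

    prov = pd.DataFrame(index=step1)
    prov["survived_step1"] = True
    prov["survived_step2"] = prov.index.isin(step2)
    prov["survived_step3"] = prov.index.isin(step3)
    prov["survived_step4"] = prov.index.isin(step4)
    prov["validated"] = prov.index.isin(validated)
    return SignaturePanel(
        genes=list(validated),
        provenance=prov,
        validation_hits=hits,
        step_counts={
            "step1": len(step1),
            "step2": len(step2),
            "step3": len(step3),
            "step4": len(step4),
            "validated": len(validated),
        },
        mode=mode,
    )
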