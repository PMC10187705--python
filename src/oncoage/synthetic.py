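"""Synthetic multi-omics cohort generator.

Emulates the statistical structure of an age-stratified thyroid-carcinoma
cohort: negative-binomial expression counts with age-group/sex/race
covariates and planted gene classes, gene-level copy-number values with an
amplified chromosome-1q-like segment, correlated binary clinical
aggressiveness parameters driven by a latent per-sample aggressiveness
score, and right-censored survival with cluster-dependent hazards.

Every random draw flows from a single :class:`numpy.random.Generator`
seeded from ``CohortConfig.seed``, so identical configurations produce
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "GENE_CLASSES",
    "ENDPOINTS",
    "CohortConfig",
    "CNVSegment",
    "OmicsCohort",
    "PlantedTruth",
    "generate_cohort",
    "generate_survival",
]

#: Planted gene classes, in block order along the gene axis.
GENE_CLASSES = (
    "shared_cancer",
    "aging_cancer_specific",
    "young_cancer_specific",
    "aging_dependent_aggressive",
    "age_independent_aggressive",
    "cnv_driven",
)

#: Survival endpoints carried per sample.
ENDPOINTS = ("DFS", "PFI", "OS", "DSS")

# Endpoint-specific multipliers of the baseline hazard.  Recurrence-type
# endpoints (DFS/PFI) are more frequent than death-type endpoints (OS/DSS)
# in differentiated thyroid carcinoma.
_ENDPOINT_HAZARD_MULT = {"DFS": 1.0, "PFI": 1.1, "OS": 0.5, "DSS": 0.25}

#: Marginal prevalence targets for the coupled binary clinical parameters
#: (tumor samples), chosen to match a papillary-thyroid-carcinoma cohort.
_PREVALENCE_TARGETS = {
    "lnm_n1": 0.50,         # N1 among staged tumors
    "ete_present": 0.34,    # present or gross extrathyroidal extension
    "ete_gross": 0.12,      # gross, conditional on present
    "hist_aggressive": 0.85,  # classical or tall-cell vs follicular variant
    "hist_tall": 0.09,      # tall-cell, conditional on aggressive
    "braf_mut": 0.60,
    "tert_mut": 0.09,
}

_IMMUNE_CELLS = [f"immune_{i:02d}" for i in range(1, 23)]


@dataclass(frozen=True)
class CNVSegment:
    """A contiguous amplified gene segment (chromosome-1q-like).

    ``start``/``end`` are gene indices (0-based, half-open).  ``None``
    places the segment over the ``cnv_driven`` gene block.
    """

    start: int | None = None
    end: int | None = None
    gain: float = 0.6
    carrier_fraction: float = 0.25


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Sample counts default to the study design they emulate: 160 aging
    (>=55 y) tumors with 19 normal counterparts, 321 young tumors with 38
    normal counterparts (481 tumors total).
    """

    n_aging_tumor: int = 160
    n_aging_normal: int = 19
    n_young_tumor: int = 321
    n_young_normal: int = 38
    n_genes: int = 1000
    class_fractions: dict = field(
        default_factory=lambda: {
            "shared_cancer": 0.05,
            "aging_cancer_specific": 0.06,
            "young_cancer_specific": 0.03,
            "aging_dependent_aggressive": 0.03,
            "age_independent_aggressive": 0.03,
            "cnv_driven": 0.02,
        }
    )
    lfc_cancer: float = 2.0
    lfc_aggressive: float = 0.5
    nb_dispersion: float = 0.3
    libsize_range: tuple = (0.7, 1.4)
    # per-parameter slopes linking the latent aggressiveness score to the
    # clinical parameters: log-odds per latent unit for binary draws,
    # linear slope for the continuous size (log-cm) and differentiation
    clinical_coupling: dict = field(
        default_factory=lambda: {
            "lnm": 1.0,
            "ete_present": 1.2,
            "ete_gross": 1.2,
            "hist_aggressive": 1.6,
            "hist_tall": 1.2,
            "braf": 1.0,
            "tert": 1.2,
            "tumor_size": 0.35,
            "differentiation": -0.5,
        }
    )
    aging_aggressiveness_shift: float = 1.0
    cnv_segment: CNVSegment = field(default_factory=CNVSegment)
    cnv_noise_sd: float = 0.1
    # residual NB dispersion of dosage-driven genes: lower than the global
    # dispersion because copy number accounts for much of their biological
    # variance (None -> use nb_dispersion)
    cnv_gene_dispersion: float | None = 0.1
    surv_baseline_hazard: float = 0.02
    surv_cluster_hr: float = 2.7
    censor_rate: float = 0.7
    force_zero_young_death_events: bool = True
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_aging_tumor,
            self.n_aging_normal,
            self.n_young_tumor,
            self.n_young_normal,
            self.n_genes,
        )
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all sample and gene counts must be positive")
        fracs = [self.class_fractions.get(c, 0.0) for c in GENE_CLASSES]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions must sum to at most 1")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.cnv_segment.carrier_fraction <= 1:
            raise ValueError("carrier fraction must lie in [0, 1]")
        if self.surv_baseline_hazard < 0 or self.surv_cluster_hr < 0:
            raise ValueError("hazard parameters must be nonnegative")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must lie in [0, 1]")


@dataclass
class OmicsCohort:
    """Aligned expression counts, CNV matrix, clinical and survival tables.

    All four tables share one sample ordering (the clinical index).
    """

    counts: pd.DataFrame      # genes x samples, nonnegative integers
    cnv: pd.DataFrame         # genes x samples, segment-mean (log2-ratio) scale
    clinical: pd.DataFrame    # samples x covariates
    survival: pd.DataFrame    # samples x {endpoint}_time/{endpoint}_event

    def validate(self) -> None:
        samples = self.clinical.index
        for name, df in (("counts", self.counts), ("cnv", self.cnv)):
            if not df.columns.equals(samples):
                raise ValueError(f"{name} columns do not match clinical sample order")
        if not self.survival.index.equals(samples):
            raise ValueError("survival index does not match clinical sample order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        imm = self.clinical[_IMMUNE_CELLS].to_numpy()
        if not np.allclose(imm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("immune fractions must sum to 1")
        tcols = [f"{e}_time" for e in ENDPOINTS]
        if (self.survival[tcols].to_numpy() <= 0).any():
            raise ValueError("survival times must be positive")

    # ------------------------------------------------------------------
    # plain-text round trip
    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.cnv.to_csv(outdir / "cnv.tsv", sep="\t", float_format="%.5f")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t")
        self.survival.to_csv(outdir / "survival.tsv", sep="\t", float_format="%.5f")

    @classmethod
    def from_dir(cls, indir: str | Path) -> "OmicsCohort":
        indir = Path(indir)
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
        cnv = pd.read_csv(indir / "cnv.tsv", sep="\t", index_col=0)
        clinical = pd.read_csv(indir / "clinical.tsv", sep="\t", index_col=0)
        survival = pd.read_csv(indir / "survival.tsv", sep="\t", index_col=0)
        return cls(counts=counts, cnv=cnv, clinical=clinical, survival=survival)


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic cohort."""

    gene_class: pd.Series          # per gene, one of GENE_CLASSES or "null"
    latent_aggressiveness: pd.Series  # per sample, continuous

    def genes_of(self, gene_class: str) -> list:
        return list(self.gene_class.index[self.gene_class == gene_class])

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_class.rename("gene_class").to_csv(outdir / "truth.tsv", sep="\t")
        self.latent_aggressiveness.rename("latent").to_csv(
            outdir / "latent.tsv", sep="\t", float_format="%.6f"
        )


# ----------------------------------------------------------------------
# helpers

def _assign_gene_classes(config: CohortConfig) -> pd.Series:
    """Disjoint contiguous index blocks per class, remainder null."""
    labels = np.array(["null"] * config.n_genes, dtype=object)
    pos = 0
    for cls in GENE_CLASSES:
        n = int(round(config.class_fractions.get(cls, 0.0) * config.n_genes))
        labels[pos : pos + n] = cls
        pos += n
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    return pd.Series(labels, index=genes, name="gene_class")


def _calibrate_intercept(latent: np.ndarray, coupling: float, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + coupling*latent)) == target."""
    f = lambda a: float(np.mean(expit(a + coupling * latent))) - target
    return brentq(f, -30.0, 30.0)


def _coupled_bernoulli(
    rng: np.random.Generator, latent: np.ndarray, coupling: float, target: float
) -> np.ndarray:
    alpha = _calibrate_intercept(latent, coupling, target)
    return rng.random(latent.size) < expit(alpha + coupling * latent)


def generate_survival(
    latent: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    young_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Exponential event times with a latent-cluster hazard ratio.

    hazard_s = baseline * endpoint_multiplier * HR^{1[latent_s > 0]}.
    Censoring is independent exponential with its rate set so the expected
    censored fraction equals ``censor_rate``.  If
    ``config.force_zero_young_death_events`` and a young mask is given,
    young samples are recoded as censored for the death endpoints (OS,
    DSS), reproducing a stratum with no death events.
    """
    if config.surv_baseline_hazard < 0 or config.surv_cluster_hr < 0:
        raise ValueError("negative hazard parameters")
    lat = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(lat)):
        raise ValueError("latent scores must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = lat.size
    high = (lat > 0).astype(float)
    out = {}
    r = config.censor_rate
    for ep in ENDPOINTS:
        lam = config.surv_baseline_hazard * _ENDPOINT_HAZARD_MULT[ep] * (
            config.surv_cluster_hr ** high
        )
        lam = np.maximum(lam, 1e-12)
        t_event = rng.exponential(1.0 / lam)
        if r >= 1.0:
            time = t_event
            event = np.zeros(n, dtype=int)
        elif r <= 0.0:
            time = t_event
            event = np.ones(n, dtype=int)
        else:
            mu = lam * r / (1.0 - r)  # P(C < T) = mu/(lam+mu) = censor_rate
            t_cens = rng.exponential(1.0 / mu)
            time = np.minimum(t_event, t_cens)
            event = (t_event <= t_cens).astype(int)
        if (
            config.force_zero_young_death_events
            and ep in ("OS", "DSS")
            and young_mask is not None
        ):
            event = np.where(np.asarray(young_mask, dtype=bool), 0, event)
        out[f"{ep}_time"] = np.maximum(time, 1e-6)
        out[f"{ep}_event"] = event
    return pd.DataFrame(out, index=latent.index if hasattr(latent, "index") else None)


def generate_cohort(config: CohortConfig) -> tuple[OmicsCohort, PlantedTruth]:
    """Draw one cohort and its planted ground truth.

    Expression model (log2 scale, before library size):

    ``log2 mu_gs = base_g + beta_g(s) + cnv coupling``

    where ``beta_g(s)`` plants, per gene class: a cancer effect of
    ``lfc_cancer`` in the aging tumor-vs-normal contrast
    (aging_cancer_specific, aging_dependent_aggressive,
    age_independent_aggressive, cnv_driven), in the young contrast
    (young_cancer_specific) or in both (shared_cancer); and an
    aggressiveness effect ``lfc_aggressive * latent_s`` in aging tumors
    only (aging_dependent_aggressive) or in all tumors
    (age_independent_aggressive).  ``cnv_driven`` counts scale
    multiplicatively with ``2**cnv``.  Counts are NB with constant
    dispersion ``nb_dispersion``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = (
        ("aging", "tumor", config.n_aging_tumor),
        ("aging", "normal", config.n_aging_normal),
        ("young", "tumor", config.n_young_tumor),
        ("young", "normal", config.n_young_normal),
    )
    age_group, tissue = [], []
    for ag, ts, n in groups:
        age_group += [ag] * n
        tissue += [ts] * n
    age_group = np.array(age_group)
    tissue = np.array(tissue)
    n_samples = age_group.size
    samples = pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample")
    aging = age_group == "aging"
    tumor = tissue == "tumor"

    # --- latent aggressiveness: higher on average in aging samples -------
    latent = config.aging_aggressiveness_shift * aging + rng.normal(size=n_samples)
    latent_s = pd.Series(latent, index=samples, name="latent")

    # --- clinical covariates --------------------------------------------
    age_years = np.where(
        aging, rng.uniform(55, 85, n_samples), rng.uniform(20, 54, n_samples)
    ).round(1)
    gender = rng.choice(["female", "male"], n_samples, p=[0.73, 0.27])
    race = rng.choice(
        ["white", "black", "asian", "other"], n_samples, p=[0.80, 0.08, 0.05, 0.07]
    )

    c = dict(config.clinical_coupling)
    lat_t = latent  # couple on all samples; analyses subset tumors
    lnm = np.where(
        _coupled_bernoulli(rng, lat_t, c["lnm"], _PREVALENCE_TARGETS["lnm_n1"]),
        "N1", "N0",
    )
    ete_present = _coupled_bernoulli(
        rng, lat_t, c["ete_present"], _PREVALENCE_TARGETS["ete_present"]
    )
    ete_gross = _coupled_bernoulli(
        rng, lat_t, c["ete_gross"], _PREVALENCE_TARGETS["ete_gross"]
    )
    ete = np.where(ete_present, np.where(ete_gross, "gross", "present"), "absent")
    hist_agg = _coupled_bernoulli(
        rng, lat_t, c["hist_aggressive"], _PREVALENCE_TARGETS["hist_aggressive"]
    )
    hist_tall = _coupled_bernoulli(
        rng, lat_t, c["hist_tall"], _PREVALENCE_TARGETS["hist_tall"]
    )
    histotype = np.where(hist_agg, np.where(hist_tall, "TPTC", "CPTC"), "FPTC")
    braf = np.where(
        _coupled_bernoulli(rng, lat_t, c["braf"], _PREVALENCE_TARGETS["braf_mut"]),
        "MUT", "WT",
    )
    tert = np.where(
        _coupled_bernoulli(rng, lat_t, c["tert"], _PREVALENCE_TARGETS["tert_mut"]),
        "MUT", "WT",
    )
    tumor_size_cm = np.exp(
        np.log(1.5) + 0.45 * rng.normal(size=n_samples) + c["tumor_size"] * latent
    ).round(2)
    # lower differentiation score = less differentiated = more aggressive
    differentiation_score = (
        c["differentiation"] * latent + rng.normal(size=n_samples)
    ).round(4)

    # immune fractions: Dirichlet; one surveillance-like compartment
    # depleted in aging samples
    conc = np.full(22, 2.0)
    conc_matrix = np.tile(conc, (n_samples, 1))
    conc_matrix[aging, 7] *= 0.6  # immune_08 depleted with age
    imm = np.vstack([rng.dirichlet(row) for row in conc_matrix])

    clinical = pd.DataFrame(
        {
            "age_years": age_years,
            "age_group": age_group,
            "tissue": tissue,
            "gender": gender,
            "race": race,
            "LNM": lnm,
            "ETE": ete,
            "tumor_size_cm": tumor_size_cm,
            "histotype": histotype,
            "BRAF": braf,
            "TERT": tert,
            "differentiation_score": differentiation_score,
        },
        index=samples,
    )
    clinical[_IMMUNE_CELLS] = imm

    # --- copy number -----------------------------------------------------
    gene_class = _assign_gene_classes(config)
    genes = gene_class.index
    cnv = rng.normal(0.0, config.cnv_noise_sd, (config.n_genes, n_samples))
    seg = config.cnv_segment
    if seg.start is None or seg.end is None:
        idx = np.where(gene_class.to_numpy() == "cnv_driven")[0]
        seg_slice = slice(idx.min(), idx.max() + 1) if idx.size else slice(0, 0)
    else:
        seg_slice = slice(seg.start, seg.end)
    aging_tumor_idx = np.where(aging & tumor)[0]
    n_carriers = int(round(seg.carrier_fraction * aging_tumor_idx.size))
    carriers = rng.choice(aging_tumor_idx, size=n_carriers, replace=False)
    seg_rows = np.arange(config.n_genes)[seg_slice]
    if seg_rows.size and carriers.size:
        cnv[np.ix_(seg_rows, carriers)] += seg.gain
    cnv = pd.DataFrame(cnv, index=genes, columns=samples)

    # --- expression counts ----------------------------------------------
    base_log2 = rng.uniform(3, 10, config.n_genes)
    beta = np.zeros((config.n_genes, n_samples))
    cls = gene_class.to_numpy()
    at = (aging & tumor).astype(float)
    yt = (~aging & tumor).astype(float)
    t = tumor.astype(float)
    for gi in range(config.n_genes):
        k = cls[gi]
        if k == "null":
            continue
        if k == "shared_cancer":
            beta[gi] = config.lfc_cancer * t
        elif k == "aging_cancer_specific":
            beta[gi] = config.lfc_cancer * at
        elif k == "young_cancer_specific":
            beta[gi] = config.lfc_cancer * yt
        elif k == "aging_dependent_aggressive":
            beta[gi] = config.lfc_cancer * at + config.lfc_aggressive * latent * at
        elif k == "age_independent_aggressive":
            beta[gi] = config.lfc_cancer * at + config.lfc_aggressive * latent * t
        elif k == "cnv_driven":
            beta[gi] = config.lfc_cancer * at + cnv.to_numpy()[gi]

    libsize = rng.uniform(*config.libsize_range, n_samples)
    mu = libsize[None, :] * np.exp2(base_log2[:, None] + beta)
    alpha = np.full(config.n_genes, config.nb_dispersion)
    if config.cnv_gene_dispersion is not None:
        alpha[cls == "cnv_driven"] = config.cnv_gene_dispersion
    # NB2: draw gamma-mixed Poisson for vectorized speed
    lam = rng.gamma(1.0 / alpha[:, None], alpha[:, None] * mu)
    counts = rng.poisson(lam).astype(np.int64)
    counts = pd.DataFrame(counts, index=genes, columns=samples)

    survival = generate_survival(
        latent_s, config, rng, young_mask=pd.Series(~aging, index=samples)
    )

    cohort = OmicsCohort(counts=counts, cnv=cnv, clinical=clinical, survival=survival)
    cohort.validate()
    truth = PlantedTruth(gene_class=gene_class, latent_aggressiveness=latent_s)
    return cohort, truth


def null_config(**overrides) -> CohortConfig:
    """A configuration with no planted signal (all gene classes empty)."""
    cfg = CohortConfig(**overrides)
    return replace(cfg, class_fractions={})
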