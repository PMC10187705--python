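# oncoage

Age-stratified tumor aggressiveness analysis for transcriptomic cohorts:
selection of aging-dependent aggressiveness gene panels, composite
PCA/RISK scoring and cluster stratification, and the copy-number,
pathway, network, survival and contingency analyses that characterize
the resulting clusters.  Built for thyroid carcinoma — the one cancer
where patient age (≥ 55 y, the AJCC 8th-edition cut-off) is itself a
staging criterion — but generic over any gene × sample count matrix with
clinical covariates.

Intended users: computational biologists studying how aging modulates
tumor phenotype, who need a reproducible implementation of
age-stratified marker selection and cluster scoring rather than a
one-off analysis script.

## The method

**Aging-dependent marker selection.**  Starting from cohort-specific
differentially expressed genes (NB-GLM likelihood-ratio tests,
padj < 0.05 and |log2FC| ≥ 1; genes DE in the aging tumor-vs-normal
contrast but not in the young or normal-aging contrasts), the pipeline
keeps genes that are

1. associated (gender/race-adjusted) with ≥ 2 of four aggressiveness
   parameters — lymph-node metastasis, extrathyroidal extension, tumor
   size ≥ 1 cm, aggressive histology;
2. directionally concordant — up in cancer and positively associated
   with aggressiveness, or the mirror image;
3. **aging-dependent** — the association is significant when adjusting
   for gender/race but vanishes (padj > 0.05) once age joins the
   adjustment;
4. internally validated — ≥ 1 significant gender/race-adjusted
   association with a wider parameter set (clinical and molecular
   markers plus DFS/PFI/OS/DSS survival) inside the aging tumor cohort
   itself.

**Composite scoring.**  A signature panel scores samples two ways: the
RISK score Σᵢ xᵢβᵢ with β from a linear-discriminant or Cox fit, and the
eigenvalue-weighted PCA aging score

    W_i = Σ_j L_ij · E_j            (components with E_j > 1)
    score_s = Σ_i z_si · W_i / Σ_i W_i

whose sign splits tumors into a more-aggressive (score > 0; MAAC/MAYC)
and a less-aggressive (LAAC/LAYC) cluster.  Cluster-by-parameter
contingency tables, Pearson-residual enrichment calls and the
aggressiveness ratio (n_aggressive − n_non)/n_parameters then rank the
four clusters.

Because the original cohorts are external, the package ships a
first-class synthetic cohort generator (`oncoage.synthetic`) with
planted gene classes, latent-aggressiveness-coupled clinical parameters,
a chromosome-1q-like CNV segment and cluster-dependent survival, so
every stage is testable by parameter recovery.  See `docs/methods.md`
for the model details and design choices.

## Worked example

```python
import warnings
from oncoage import CohortConfig, generate_cohort, run_signature_pipeline
from oncoage.scores import fit_pca_aging, pca_aging_score, stratify

cohort, truth = generate_cohort(CohortConfig(seed=1))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    panel = run_signature_pipeline(cohort)
print(panel.step_counts)

clin = cohort.clinical
aging_tumors = clin[(clin.tissue == "tumor") & (clin.age_group == "aging")]
expr = cohort.counts.loc[panel.genes, aging_tumors.index].T
model = fit_pca_aging(expr)
scores = pca_aging_score(expr, model)
print(stratify(scores).labels.value_counts().to_dict())

planted = set(truth.genes_of("aging_dependent_aggressive"))
print(f"recall: {len(planted & set(panel.genes)) / len(planted):.2f}")
```

prints

```
{'step1': 140, 'step2': 140, 'step3': 140, 'step4': 114, 'validated': 28}
{'LAAC': 93, 'MAAC': 67}
recall: 0.77
```

— the 1000-gene cohort yields 140 aging-cancer-specific candidates, 114
survive the aging-dependence filter, 28 validate internally (recovering
77 % of the 30 planted aging-dependent aggressive genes on this seed),
and the PCA aging score splits the 160 aging tumors into less/more
aggressive clusters of 93 and 67.

A command-line interface wraps the same library:

```bash
oncoage simulate --seed 1 --outdir cohort/
oncoage dge --cohort cohort/ --contrast tissue~normal --adjust gender,race --out de.tsv
oncoage select-signature --cohort cohort/ --mode aging --out panel.tsv
```

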