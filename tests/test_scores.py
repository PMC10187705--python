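"""Composite scores: LDA risk score, PCA aging score, stratification."""

import numpy as np
import pandas as pd
import pytest

from oncoage.scores import (
    RiskScoreModel,
    fit_lda,
    fit_pca_aging,
    pca_aging_score,
    risk_score,
    stratify,
)


def _frame(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestLDA:
    def test_one_dimensional_closed_form(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(0, 1, 200)
        x1 = rng.normal(2, 1, 200)
        x = _frame(np.concatenate([x0, x1])[:, None])
        beta = fit_lda(x, [0] * 200 + [1] * 200)
        # beta = (mean diff)/pooled variance ~ 2/1
        assert beta.iloc[0] == pytest.approx(2.0, abs=0.35)

    def test_identical_class_means_zero_direction(self):
        x = _frame([[1, 2], [3, 1], [1, 2], [3, 1]])
        beta = fit_lda(x, [0, 0, 1, 1])
        assert np.linalg.norm(beta) < 1e-6

    def test_gene_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        x = _frame(rng.normal(size=(40, 5)))
        y = [0] * 20 + [1] * 20
        beta = fit_lda(x, y)
        perm = ["g3", "g0", "g4", "g1", "g2"]
        beta_p = fit_lda(x[perm], y)
        assert np.allclose(beta[perm].to_numpy(), beta_p.to_numpy())

    def test_matches_sklearn_direction(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(2)
        x = _frame(rng.normal(size=(60, 4)))
        y = np.array([0] * 30 + [1] * 30)
        x.iloc[30:, 0] += 1.0
        beta = fit_lda(x, y).to_numpy()
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(x, y).coef_.ravel()
        cos = beta @ ref / (np.linalg.norm(beta) * np.linalg.norm(ref))
        assert cos > 0.999  # same discriminant direction

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(_frame(np.eye(4)), [1, 1, 1, 1])


class TestRiskScore:
    def test_zero_coefficients_zero_scores(self):
        model = RiskScoreModel("LNM", pd.Series([0.0, 0.0], index=["g0", "g1"]))
        s = risk_score(_frame([[5, 3], [2, 8]]), model)
        assert (s == 0).all()

    def test_single_gene_product(self):
        model = RiskScoreModel("LNM", pd.Series([1.5], index=["g0"]))
        s = risk_score(_frame([[2.0]]), model)
        assert s.iloc[0] == pytest.approx(3.0)

    def test_linearity_in_beta(self):
        rng = np.random.default_rng(3)
        expr = _frame(rng.normal(size=(10, 3)))
        beta = pd.Series(rng.normal(size=3), index=expr.columns)
        s1 = risk_score(expr, RiskScoreModel("p", beta))
        s2 = risk_score(expr, RiskScoreModel("p", 2.5 * beta))
        assert np.allclose(2.5 * s1, s2)

    def test_missing_gene_raises_with_names(self):
        model = RiskScoreModel("p", pd.Series([1.0, 1.0], index=["g0", "missing"]))
        with pytest.raises(KeyError, match="missing"):
            risk_score(_frame([[1.0]]), model)

    def test_discriminates_planted_phenotype(self, default_cohort):
        cohort, truth = default_cohort
        clin = cohort.clinical
        mask = (clin["tissue"] == "tumor") & (clin["age_group"] == "aging")
        genes = truth.genes_of("aging_dependent_aggressive")
        expr = np.log2(cohort.counts.loc[genes, clin[mask].index] + 1).T
        y = (truth.latent_aggressiveness[clin[mask].index] > 0).astype(int)
        beta = fit_lda(expr, y)
        s = risk_score(expr, RiskScoreModel("latent", beta))
        from oncoage.stats import roc_metrics

        assert roc_metrics(s.to_numpy(), y.to_numpy()).auc > 0.8


class TestPCAAging:
    def test_two_correlated_genes_reduce_to_mean_zscore(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        expr = _frame(np.column_stack([x, 3 * x - 1]))
        model = fit_pca_aging(expr)
        assert model.all_eigenvalues.to_numpy() == pytest.approx([2.0, 0.0], abs=1e-9)
        assert list(model.eigenvalues.index) == ["PC1"]
        assert model.loadings["PC1"].to_numpy() == pytest.approx(
            [1 / np.sqrt(2)] * 2
        )
        assert model.weights.to_numpy() == pytest.approx([np.sqrt(2)] * 2)
        s = pca_aging_score(expr, model)
        z = (expr - expr.mean()) / expr.std(ddof=1)
        assert np.allclose(s, z.mean(axis=1))

    def test_degenerate_panels_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            fit_pca_aging(_frame(rng.normal(size=(20, 1))))  # single gene
        # two independent genes: eigenvalues straddle 1 barely; force a
        # clean boundary with exactly uncorrelated columns
        x = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        with pytest.raises(ValueError, match="eigenvalue > 1"):
            fit_pca_aging(_frame(x))

    def test_zero_variance_gene_named(self):
        expr = _frame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="g1"):
            fit_pca_aging(expr)

    def test_matches_bruteforce_pca_oracle(self):
        # independent eigen-decomposition oracle on a two-block panel
        rng = np.random.default_rng(6)
        b1 = rng.normal(size=(80, 1)) + 0.3 * rng.normal(size=(80, 3))
        b2 = rng.normal(size=(80, 1)) + 0.3 * rng.normal(size=(80, 3))
        expr = _frame(np.hstack([b1, b2]))
        model = fit_pca_aging(expr)
        Z = ((expr - expr.mean()) / expr.std(ddof=1)).to_numpy()
        evals, evecs = np.linalg.eigh(np.corrcoef(Z, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        keep = evals > 1
        L = evecs[:, keep] * np.where(evecs[:, keep].sum(axis=0) >= 0, 1, -1)
        W = L @ evals[keep]
        oracle = Z @ W / W.sum()
        mine = pca_aging_score(expr, model).to_numpy()
        assert np.allclose(mine, oracle)
        assert np.array_equal(np.argsort(mine), np.argsort(oracle))

    def test_score_identities(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(50, 1))
        expr = _frame(np.hstack([base, base + 0.2 * rng.normal(size=(50, 1))]))
        model = fit_pca_aging(expr)
        s = pca_aging_score(expr, model)
        assert abs(s.mean()) < 1e-9  # training mean is zero
        at_means = pd.DataFrame([expr.mean()], index=["new"])
        assert pca_aging_score(at_means, model).iloc[0] == pytest.approx(0.0)

    def test_equal_weight_formula_evaluation(self):
        model_means = pd.Series([0.0, 0.0], index=["g0", "g1"])
        model_sds = pd.Series([1.0, 1.0], index=["g0", "g1"])
        from oncoage.scores import PCAAgingModel

        model = PCAAgingModel(
            means=model_means, sds=model_sds,
            loadings=pd.DataFrame({"PC1": [0.7071, 0.7071]}, index=["g0", "g1"]),
            eigenvalues=pd.Series({"PC1": 2.0}),
            weights=pd.Series([1.0, 1.0], index=["g0", "g1"]),
        )
        expr = pd.DataFrame([[1.0, -1.0], [2.0, 0.0]], columns=["g0", "g1"])
        s = pca_aging_score(expr, model)
        assert s.to_numpy() == pytest.approx([0.0, 1.0])

    def test_invariance_to_gene_order_and_shift(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(40, 1))
        expr = _frame(base + 0.3 * rng.normal(size=(40, 4)))
        s = pca_aging_score(expr, fit_pca_aging(expr))
        perm = list(expr.columns[::-1])
        s_perm = pca_aging_score(expr[perm], fit_pca_aging(expr[perm]))
        assert np.allclose(s, s_perm)
        shifted = expr.copy()
        shifted["g0"] = shifted["g0"] + 100.0
        s_shift = pca_aging_score(shifted, fit_pca_aging(shifted))
        assert np.allclose(s, s_shift)


class TestStratify:
    def test_sign_rule(self):
        out = stratify(pd.Series([1.2, -0.3]))
        assert list(out.labels) == ["MAAC", "LAAC"]

    def test_zero_goes_less_aggressive(self):
        assert stratify(pd.Series([0.0])).labels.iloc[0] == "LAAC"

    def test_all_positive_degenerate_but_legal(self):
        out = stratify(pd.Series([0.5, 1.0, 2.0]))
        assert (out.labels == "MAAC").all()

    def test_young_mode_labels(self):
        out = stratify(pd.Series([1.0, -1.0]), mode="young")
        assert list(out.labels) == ["MAYC", "LAYC"]

    def test_planted_two_cluster_recovery(self):
        # 1-SD mean shift on panel genes for half the samples
        rng = np.random.default_rng(9)
        n, p = 200, 10
        member = np.repeat([0, 1], n // 2)
        expr = _frame(member[:, None] * 1.0 + rng.normal(size=(n, p)))
        model = fit_pca_aging(expr)
        s = pca_aging_score(expr, model)
        labels = stratify(s).labels
        acc = max(
            ((labels == "MAAC") == (member == 1)).mean(),
            ((labels == "MAAC") == (member == 0)).mean(),
        )
        assert acc >= 0.85
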