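"""Gene-set over-representation, agglomerate z, ssGSEA, selection filters."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from oncoage.pathways import (
    agglomerate_zscore,
    aging_specificity_filter,
    compare_nes,
    ora_enrichment,
    read_gmt,
    select_condition_pathways,
    ssgsea_nes,
    write_gmt,
)


def _expr(rng, n_genes=30, n_samples=12):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


def test_gmt_roundtrip(tmp_path):
    sets = {"A": ["g1", "g2"], "B": ["g3", "g4", "g5"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets


def test_gmt_rejects_empty_and_duplicate(tmp_path):
    p = tmp_path / "bad.gmt"
    p.write_text("A\tdesc\t\n")
    with pytest.raises(ValueError):
        read_gmt(p)
    p.write_text("A\tdesc\tg1\nA\tdesc\tg2\n")
    with pytest.raises(ValueError):
        read_gmt(p)


class TestORA:
    def test_matches_exact_enumeration_oracle(self):
        # hypergeometric tail recomputed from binomial coefficients
        universe = [f"g{i}" for i in range(18)]
        coll = {"S": universe[:6]}
        degs = universe[:4] + universe[10:12]  # overlap 4 of 6
        out = ora_enrichment(degs, coll, universe)
        N, K, n, k = 18, 6, 6, 4
        p_exact = sum(
            comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
        ) / comb(N, n)
        assert out.loc["S", "pvalue"] == pytest.approx(p_exact)
        assert out.loc["S", "overlap"] == 4

    def test_full_pathway_hit_is_minimal_p(self):
        universe = [f"g{i}" for i in range(20)]
        coll = {"A": universe[:5], "B": universe[10:18]}
        out = ora_enrichment(universe[:5], coll, universe)
        assert out["pvalue"].idxmin() == "A"
        assert out.loc["A", "fold"] == pytest.approx(20 / 5)

    def test_random_set_p_uniform(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        coll = {"A": universe[:30]}
        pvals = [
            ora_enrichment(list(rng.choice(universe, 20, replace=False)), coll, universe)
            .loc["A", "pvalue"]
            for _ in range(50)
        ]
        assert np.mean(np.array(pvals) < 0.05) <= 0.15

    def test_empty_deg_set_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment([], {"A": ["g1"]}, ["g1"])

    def test_deg_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(["x"], {"A": ["g1"]}, ["g1"])


class TestAgglomerateZ:
    def test_sample_at_gene_means_scores_zero(self, rng):
        expr = _expr(rng)
        expr["s0"] = expr.mean(axis=1)  # make s0 sit at every gene mean
        s = agglomerate_zscore(expr, ["g0", "g1", "g2"])
        # s0's z on every member gene is ~0 relative to the new means
        assert abs(s["s0"]) < 0.3

    def test_direct_mean_of_member_zscores(self, rng):
        expr = _expr(rng, n_genes=4)
        s = agglomerate_zscore(expr, ["g0", "g1"])
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
        assert np.allclose(s, z.loc[["g0", "g1"]].mean(axis=0))
        assert abs(s.mean()) < 1e-9  # column mean zero over training samples

    def test_no_overlap_rejected(self, rng):
        with pytest.raises(ValueError):
            agglomerate_zscore(_expr(rng), ["absent"])

    def test_alternative_methods(self, rng):
        expr = _expr(rng)
        s_mean = agglomerate_zscore(expr, ["g0", "g1"], method="mean")
        s_sum = agglomerate_zscore(expr, ["g0", "g1"], method="sum")
        assert np.allclose(2 * s_mean, s_sum)


class TestConditionSelection:
    def test_planted_shift_selected_with_direction(self, rng):
        scores = pd.DataFrame(
            {f"s{j}": [rng.normal() + (1.0 if j >= 100 else 0.0)] for j in range(200)},
            index=["path_up"],
        )
        cond = ["a"] * 100 + ["b"] * 100
        out = select_condition_pathways(scores, cond)
        assert "path_up" in out.index
        assert out.loc["path_up", "direction"] == 1.0

    def test_null_score_not_selected(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(3, 200)), index=["p1", "p2", "p3"]
        )
        cond = ["a"] * 100 + ["b"] * 100
        out = select_condition_pathways(scores, cond)
        assert len(out) == 0

    def test_single_level_condition_rejected(self, rng):
        scores = pd.DataFrame(rng.normal(size=(1, 10)), index=["p"])
        with pytest.raises(ValueError):
            select_condition_pathways(scores, ["a"] * 10)


class TestSpecificityFilter:
    def _sel(self, names, directions):
        return pd.DataFrame(
            {"direction": directions, "padj": [0.01] * len(names)}, index=names
        )

    def test_aging_only_pathway_kept(self, rng):
        sa = self._sel(["p1"], [1.0])
        sy = self._sel([], [])
        scores = pd.DataFrame(rng.normal(size=(1, 10)), index=["p1"])
        out = aging_specificity_filter(sa, sy, scores, scores)
        assert list(out.index) == ["p1"]

    def test_shared_same_direction_similar_scores_removed(self, rng):
        sa = self._sel(["p1"], [1.0])
        sy = self._sel(["p1"], [1.0])
        scores = pd.DataFrame(rng.normal(size=(1, 50)), index=["p1"])
        out = aging_specificity_filter(sa, sy, scores, scores + 0.001)
        assert len(out) == 0

    def test_opposite_direction_kept(self, rng):
        sa = self._sel(["p1"], [1.0])
        sy = self._sel(["p1"], [-1.0])
        scores = pd.DataFrame(rng.normal(size=(1, 50)), index=["p1"])
        out = aging_specificity_filter(sa, sy, scores, scores)
        assert list(out.index) == ["p1"]

    def test_shared_but_different_scores_kept(self, rng):
        sa = self._sel(["p1"], [1.0])
        sy = self._sel(["p1"], [1.0])
        scores_a = pd.DataFrame(rng.normal(size=(1, 50)) + 3.0, index=["p1"])
        scores_y = pd.DataFrame(rng.normal(size=(1, 50)), index=["p1"])
        out = aging_specificity_filter(sa, sy, scores_a, scores_y)
        assert list(out.index) == ["p1"]  # Kruskal p < 0.05 between cohorts


class TestSSGSEA:
    def test_top_set_scores_above_bottom_set(self, rng):
        expr = _expr(rng, n_genes=40, n_samples=3)
        col = expr.iloc[:, 0]
        top = col.nlargest(6).index
        bottom = col.nsmallest(6).index
        nt = ssgsea_nes(expr, top, rescale=False)
        nb = ssgsea_nes(expr, bottom, rescale=False)
        assert nt.iloc[0] > nb.iloc[0]

    def test_rank_only_variant_monotone_invariant(self, rng):
        expr = _expr(rng, n_genes=25, n_samples=4)
        s1 = ssgsea_nes(expr, list(expr.index[:5]), weight=0.0, rescale=False)
        s2 = ssgsea_nes(np.exp(expr * 2), list(expr.index[:5]), weight=0.0, rescale=False)
        assert np.allclose(s1, s2)

    def test_five_gene_toy_matches_bruteforce_running_sum(self):
        expr = pd.DataFrame(
            {"s0": [5.0, 4.0, 3.0, 2.0, 1.0]},
            index=["a", "b", "c", "d", "e"],
        )
        members = {"a", "c"}
        w = 0.25
        # brute-force running sum over the explicit ranking a>b>c>d>e
        rank_vals = np.array([5.0, 4.0, 3.0, 2.0, 1.0]) ** w
        hits = np.array([1, 0, 1, 0, 0], dtype=float)
        cdf_in = np.cumsum(rank_vals * hits) / (rank_vals * hits).sum()
        cdf_out = np.cumsum(1 - hits) / 3
        expected = float(np.sum(cdf_in - cdf_out))
        got = ssgsea_nes(expr, members, weight=w, rescale=False)
        assert got.iloc[0] == pytest.approx(expected)

    def test_rescaled_scores_span_unit_interval(self, rng):
        expr = _expr(rng, n_genes=30, n_samples=8)
        s = ssgsea_nes(expr, list(expr.index[:5]))
        assert s.min() == 0.0 and s.max() == 1.0

    def test_insufficient_overlap_rejected(self, rng):
        with pytest.raises(ValueError):
            ssgsea_nes(_expr(rng), ["g0"])


class TestCompareNES:
    def test_null_and_planted(self, rng):
        null = pd.DataFrame(rng.normal(size=(1, 60)), index=["p_null"],
                            columns=[f"s{j}" for j in range(60)])
        shift = null.copy()
        shift.iloc[0, 30:] += 2.0
        shift.index = ["p_shift"]
        nes = pd.concat([null, shift])
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=null.columns)
        out = compare_nes(nes, groups)
        assert out.loc["p_shift", "padj"] < 0.05
        assert out.loc["p_null", "pvalue"] > 0.01

    def test_single_group_rejected(self, rng):
        nes = pd.DataFrame(rng.normal(size=(1, 10)), index=["p"],
                           columns=[f"s{j}" for j in range(10)])
        with pytest.raises(ValueError):
            compare_nes(nes, pd.Series(["a"] * 10, index=nes.columns))

    def test_tiny_groups_flagged(self, rng):
        nes = pd.DataFrame(rng.normal(size=(1, 5)), index=["p"],
                           columns=[f"s{j}" for j in range(5)])
        groups = pd.Series(["a", "a", "b", "b", "b"], index=nes.columns)
        out = compare_nes(nes, groups)
        assert out["flag"].iloc[0] == "small_group"
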