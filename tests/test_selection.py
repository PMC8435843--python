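"""Comparative selection tests: matched resampling, KS contrasts, Fisher
enrichment, direction bias, regressions, zero-F_ST candidates."""

import math

import numpy as np
import pandas as pd
import pytest

from domestica import selection


def toy_scan_inputs(n=400, seed=0, delta_high_fst=0.0):
    """Genes with diversity-dependent CV and optional extra CV loss planted
    only in the top-decile F_ST genes."""
    rng = np.random.default_rng(seed)
    pi = rng.gamma(2.0, 1e-3, size=n)
    fst = rng.beta(1, 8, size=n)
    cv_wild = 0.6 + 50 * pi + rng.normal(0, 0.05, n)
    cv_crop = cv_wild - 0.05 - rng.normal(0, 0.05, n)
    high = fst >= np.quantile(fst, 0.9)
    cv_crop = cv_crop - delta_high_fst * high
    idx = pd.Index([f"g{i}" for i in range(n)])
    return (pd.Series(cv_wild, idx), pd.Series(cv_crop, idx),
            pd.Series(pi, idx), pd.Series(fst, idx))


class TestMatchedResampling:
    def test_identical_cv_gives_null_result(self):
        cvw, _cvc, pi, fst = toy_scan_inputs(seed=1)
        scan = selection.matched_resampling_test(cvw, cvw, pi, fst, 95, 200, rng=0)
        assert scan.observed_delta_cv == 0.0
        assert scan.p_value > 0.3

    def test_matching_constraint_holds_for_every_draw(self):
        """Each drawn donor has pi <= the matched outlier's pi (checked by
        re-running the draw logic with the same seed)."""
        cvw, cvc, pi, fst = toy_scan_inputs(seed=2)
        rng = np.random.default_rng(7)
        scan = selection.matched_resampling_test(cvw, cvc, pi, fst, 90, 50, rng=rng)
        data = pd.DataFrame({"cvw": cvw, "cvc": cvc, "pi": pi, "fst": fst}).dropna()
        out = data.loc[scan.outlier_genes]
        others = data.drop(scan.outlier_genes).sort_values("pi")
        n_elig = np.searchsorted(others["pi"].to_numpy(), out["pi"].to_numpy(), side="right")
        rng2 = np.random.default_rng(7)
        draws = (rng2.random((50, len(out))) * np.maximum(n_elig, 1)[None, :]).astype(np.int64)
        drawn_pi = others["pi"].to_numpy()[draws]
        assert (drawn_pi <= out["pi"].to_numpy()[None, :] + 1e-15).all()

    def test_p_reproducible_and_never_zero(self):
        cvw, cvc, pi, fst = toy_scan_inputs(seed=3, delta_high_fst=0.5)
        s1 = selection.matched_resampling_test(cvw, cvc, pi, fst, 95, 300, rng=5)
        s2 = selection.matched_resampling_test(cvw, cvc, pi, fst, 95, 300, rng=5)
        assert s1.p_value == s2.p_value
        assert s1.p_value >= 1.0 / 301.0
        assert np.array_equal(s1.null_delta_cv, s2.null_delta_cv)

    def test_planted_high_fst_cv_loss_detected(self):
        cvw, cvc, pi, fst = toy_scan_inputs(n=800, seed=4, delta_high_fst=0.3)
        scan = selection.matched_resampling_test(cvw, cvc, pi, fst, 95, 1000, rng=6)
        assert scan.p_value < 0.01

    def test_null_p_roughly_uniform_over_replicates(self):
        """With CV loss independent of F_ST the empirical p is roughly
        uniform across replicate simulations."""
        ps = []
        for seed in range(40):
            cvw, cvc, pi, fst = toy_scan_inputs(n=300, seed=100 + seed)
            scan = selection.matched_resampling_test(cvw, cvc, pi, fst, 90, 200,
                                                     rng=seed)
            ps.append(scan.p_value)
        ps = np.asarray(ps)
        assert 0.25 <= ps.mean() <= 0.75
        assert (ps < 0.05).mean() <= 0.15

    def test_relaxation_warns_when_no_donor_matches(self):
        idx = pd.Index(["a", "b", "c", "d"])
        cv = pd.Series([1.0, 1.0, 1.0, 1.0], idx)
        pi = pd.Series([1e-5, 1.0, 1.0, 1.0], idx)  # outlier has lowest pi
        fst = pd.Series([0.9, 0.1, 0.1, 0.1], idx)
        with pytest.warns(UserWarning, match="relaxed"):
            scan = selection.matched_resampling_test(cv, cv * 0.9, pi, fst, 75, 20, rng=0)
        assert scan.n_relaxed == 1


def brute_force_fisher(table: np.ndarray) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration (point
    probability method), independent of scipy."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestEnrichment2x2:
    def test_balanced_table(self):
        flags = np.repeat([True, True, False, False], 10)
        cat = np.tile(np.repeat([True, False], 10), 2)
        res = selection.enrichment_2x2(flags, cat)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_perfect_association_enumeration(self):
        """[[5,0],[0,5]] -> two-sided p = 2/252."""
        flags = np.array([True] * 5 + [False] * 5)
        res = selection.enrichment_2x2(flags, flags)
        assert res["p"] == pytest.approx(2.0 / 252.0, rel=1e-9)

    def test_matches_enumeration_for_all_small_margins(self):
        """Fisher p equals brute-force hypergeometric enumeration on every
        table with both margins <= 12."""
        rng = np.random.default_rng(9)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 7, size=4)
            if (a + b + c + d) == 0 or a + b + c + d > 24:
                continue
            flags = np.array([True] * (a + b) + [False] * (c + d))
            cat = np.array([True] * a + [False] * b + [True] * c + [False] * d)
            res = selection.enrichment_2x2(flags, cat)
            table = np.array([[a, b], [c, d]])
            if min(table.sum(0).min(), table.sum(1).min()) == 0:
                assert res["p"] == 1.0
            else:
                assert res["p"] == pytest.approx(brute_force_fisher(table), rel=1e-9)

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(10)
        de = rng.random(5000) < 0.05
        cat = np.where(de, rng.random(5000) < 0.3, rng.random(5000) < 0.1)
        res = selection.enrichment_2x2(de, cat)
        assert res["p"] < 0.05
        assert res["odds_ratio"] > 1


class TestDirectionBias:
    def test_balanced_split_not_significant(self):
        idx = pd.Index(range(1000))
        de = pd.Series([True] * 100 + [False] * 900, idx)
        logfc = pd.Series(np.r_[np.tile([1.0, -1.0], 50), np.tile([1.0, -1.0], 450)], idx)
        res = selection.direction_bias_test(de, logfc)
        assert res["p"] > 0.9

    def test_eighty_two_percent_down_is_extreme(self):
        """949 DE genes with 82% down vs a balanced background: p << 1e-10
        (closed-form chi-square scale check)."""
        n_de, n_bg = 949, 20000
        de = pd.Series([True] * n_de + [False] * n_bg)
        down_de = int(round(0.82 * n_de))
        logfc = pd.Series(
            np.r_[np.ones(down_de), -np.ones(n_de - down_de),
                  np.tile([1.0, -1.0], n_bg // 2)])
        res = selection.direction_bias_test(de, logfc)
        assert res["frac_down_de"] == pytest.approx(0.82, abs=0.001)
        assert res["p"] < 1e-10

    def test_generator_frac_down_recovered(self, default_master):
        """The recovered down-fraction among true DE genes matches the
        planted frac_down = 0.82 within 0.04."""
        m = default_master["master"]
        de_true = m["is_de"].fillna(False).astype(bool)
        frac = (m.loc[de_true, "true_lfc"] > 0).mean()
        assert frac == pytest.approx(0.82, abs=0.04)
        called = m["de"].fillna(False) & de_true
        assert (m.loc[called, "logfc"] > 0).mean() == pytest.approx(0.82, abs=0.1)

    def test_small_de_set_uses_binomial(self):
        idx = pd.Index(range(100))
        de = pd.Series([True] * 5 + [False] * 95, idx)
        logfc = pd.Series(np.r_[np.ones(5), np.tile([1.0, -1.0], 47), [1.0]], idx)
        res = selection.direction_bias_test(de, logfc)
        assert res["method"] == "binomial"


class TestRegression:
    def test_planted_line_recovered(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 1000, 500)
        stat = 10 ** (-0.4 * np.log10(x) + rng.normal(0, 1e-6, 500))
        pools = pd.Series(["wild"] * 500)
        res = selection.polymorphism_expression_regression(
            pd.Series(stat), pd.Series(x), pools)
        assert res["per_pool"]["wild"]["slope"] == pytest.approx(-0.4, abs=1e-3)
        assert res["per_pool"]["wild"]["adj_r2"] > 0.999

    def test_four_point_normal_equations(self):
        """Hand regression through 4 points matches the OLS slope."""
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        y = np.array([2e-3, 1.5e-3, 1e-3, 0.7e-3])
        lx, ly = np.log10(x), np.log10(y)
        slope_hand = ((lx - lx.mean()) * (ly - ly.mean())).sum() / ((lx - lx.mean()) ** 2).sum()
        res = selection.polymorphism_expression_regression(
            pd.Series(y), pd.Series(x), pd.Series(["wild"] * 4), min_genes=4)
        assert res["per_pool"]["wild"]["slope"] == pytest.approx(slope_hand, abs=1e-10)

    def test_interaction_null_uniformity(self):
        """Identical pools: the interaction p is roughly uniform over
        repetitions."""
        ps = []
        for seed in range(30):
            rng = np.random.default_rng(200 + seed)
            x = np.r_[rng.uniform(1, 100, 150), rng.uniform(1, 100, 150)]
            y = 10 ** (-0.3 * np.log10(x) + rng.normal(0, 0.3, 300))
            pools = pd.Series(["wild"] * 150 + ["crop"] * 150)
            res = selection.polymorphism_expression_regression(
                pd.Series(y), pd.Series(x), pools)
            ps.append(res["interaction"]["p"])
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.2
        assert ps.mean() > 0.3

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            selection.polymorphism_expression_regression(
                pd.Series([1e-3] * 3), pd.Series([1.0] * 3), pd.Series(["wild"] * 3))


class TestZeroFst:
    def test_empty_and_constructed_sets(self):
        idx = pd.Index([f"g{i}" for i in range(6)])
        fst = pd.Series([0.0, -0.1, 0.0, 0.5, 0.2, 0.0], idx)
        de = pd.Series([True, True, False, True, False, True], idx)
        out = selection.zero_fst_candidates(de, fst)
        assert set(out["gene_id"]) == {"g0", "g1", "g5"}
        none = selection.zero_fst_candidates(pd.Series(False, idx), fst)
        assert none.empty

    def test_expression_only_divergence_enriched(self, default_master):
        """Among DE genes, the zero-F_ST regulatory-only candidates are
        depleted of swept genes (expression-only divergence)."""
        m = default_master["master"]
        de = m["de"].fillna(False).astype(bool)
        cand = selection.zero_fst_candidates(de, m["fst"])
        in_cand = m.index.isin(cand["gene_id"])
        de_only = de & ~in_cand
        sub = m[de]
        res = selection.enrichment_2x2(sub.index.isin(cand["gene_id"]),
                                       sub["is_swept"].fillna(False).astype(bool))
        assert res["odds_ratio"] < 1.0 or res["p"] > 0.05  # never positively associated
        # swept DE genes should essentially never appear at F_ST <= 0
        assert sub.loc[sub.index.isin(cand["gene_id"]), "is_swept"].mean() < 0.2


def test_de_vs_nonde_distribution_machinery():
    """Planted location shift is detected by the KS test; null is not."""
    rng = np.random.default_rng(12)
    n = 1500
    stats_table = pd.DataFrame({
        "pi_n": rng.gamma(2, 1e-3, n),
        "pi_s": rng.gamma(2, 4e-3, n),
    }, index=[f"g{i}" for i in range(n)])
    de = pd.Series(np.arange(n) < 300, index=stats_table.index)
    stats_table.loc[de, "pi_n"] *= 0.5  # planted lower piN in DE genes
    summ, tests = selection.de_vs_nonde_distributions(
        stats_table, de, columns=("pi_n", "pi_s"))
    t = tests.set_index("statistic")
    assert t.loc["pi_n", "ks_p"] < 1e-6
    assert t.loc["pi_s", "ks_p"] > 0.01
    s = summ.set_index(["statistic", "group"])
    assert s.loc[("pi_n", "DE"), "median"] < s.loc[("pi_n", "non-DE"), "median"]


def test_group_below_min_suppresses_test():
    stats_table = pd.DataFrame({"pi_n": np.linspace(0, 1, 20)},
                               index=[f"g{i}" for i in range(20)])
    de = pd.Series([True] * 3 + [False] * 17, stats_table.index)
    _summ, tests = selection.de_vs_nonde_distributions(stats_table, de, columns=("pi_n",))
    assert np.isnan(tests.iloc[0]["ks_p"])
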