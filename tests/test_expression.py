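"""Expression processing: CPM filter, TMM, CV, exact tests, BH, PCA."""

import numpy as np
import pandas as pd
import pytest

from domestica.expression import (
    bh_adjust, cpm, exact_test_de, expression_cv, expression_pca,
    filter_expressed, tmm_factors,
)
from domestica.simulate import SimulationParams, simulate_counts


def frame(arr, cols=None):
    arr = np.asarray(arr)
    cols = cols or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols)


def labels_for(cols, n_wild):
    return pd.Series(["wild"] * n_wild + ["crop"] * (len(cols) - n_wild), index=cols, name="pool")


class TestFilter:
    def test_hand_enumerated_retained_set(self):
        """Toy matrix with known CPMs: a gene needs CPM >= 1 in >= 2
        accessions here (thresholds scaled for the toy)."""
        counts = frame([
            [100, 100, 100],   # well expressed everywhere
            [0, 0, 0],         # all-zero: removed
            [1, 0, 0],         # CPM >= 1 in one accession only
            [5, 5, 0],         # two accessions
        ])
        lab = labels_for(counts.columns, 2)
        kept = filter_expressed(counts, lab, min_accessions=2, min_cpm=1.0)
        lib = counts.sum()
        manual = ((counts / lib * 1e6 >= 1).sum(axis=1) >= 2)
        assert list(kept.index) == list(counts.index[manual])
        assert "g1" not in kept.index

    def test_boundary_exactly_five_accessions(self):
        rng = np.random.default_rng(0)
        counts = frame(rng.poisson(50, size=(20, 20)))
        counts.iloc[0] = 0
        counts.iloc[0, :5] = 2000  # CPM >= 1 in exactly 5 accessions
        lab = labels_for(counts.columns, 9)
        kept = filter_expressed(counts, lab, min_accessions=5, min_cpm=1.0)
        assert "g0" in kept.index

    def test_unlabeled_accession_rejected(self):
        counts = frame([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            filter_expressed(counts, pd.Series({"s0": "wild"}))


def reference_tmm(counts: np.ndarray, obs: int, ref: int,
                  trim_m=0.30, trim_a=0.05) -> float:
    """Independent step-by-step TMM of sample ``obs`` against ``ref``."""
    n_o, n_r = counts[:, obs].sum(), counts[:, ref].sum()
    keep = (counts[:, obs] > 0) & (counts[:, ref] > 0)
    y_o, y_r = counts[keep, obs], counts[keep, ref]
    m = np.log2((y_o / n_o) / (y_r / n_r))
    a = 0.5 * np.log2((y_o / n_o) * (y_r / n_r))
    w = (n_o - y_o) / (n_o * y_o) + (n_r - y_r) / (n_r * y_r)
    sel = np.ones(len(m), bool)
    lo, hi = np.quantile(m, [trim_m, 1 - trim_m])
    sel &= (m >= lo) & (m <= hi)
    lo, hi = np.quantile(a, [trim_a, 1 - trim_a])
    sel &= (a >= lo) & (a <= hi)
    return 2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))


class TestTMM:
    def test_identical_and_depth_scaled_libraries(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=200)
        counts = frame(np.column_stack([base, base]))
        assert np.allclose(tmm_factors(counts), 1.0)
        counts = frame(np.column_stack([base, base * 2]))
        assert np.allclose(tmm_factors(counts), 1.0)  # pure depth, factor stays 1

    def test_asymmetric_shift_matches_reference_implementation(self):
        """10% of genes 8-fold up in sample B: the factor ratio matches the
        hand-rolled reference TMM on 50 genes."""
        rng = np.random.default_rng(2)
        a = rng.poisson(200, size=50).astype(float)
        b = a.copy()
        b[:5] *= 8
        counts = frame(np.column_stack([a, b]))
        got = tmm_factors(counts)
        # the factor RATIO is invariant to the geometric-mean rescaling,
        # whichever sample was chosen as reference
        expect = reference_tmm(counts.to_numpy(float), obs=1, ref=0)
        alt = 1.0 / reference_tmm(counts.to_numpy(float), obs=0, ref=1)
        ratio = got.iloc[1] / got.iloc[0]
        assert min(abs(ratio - expect), abs(ratio - alt)) < 1e-9 * max(expect, alt)

    def test_invariant_to_global_library_scaling(self):
        rng = np.random.default_rng(3)
        counts = frame(rng.poisson(80, size=(300, 6)))
        f1 = tmm_factors(counts)
        f2 = tmm_factors(counts * 5)
        assert np.allclose(f1, f2, rtol=1e-9)


class TestBH:
    def test_step_up_by_hand(self):
        """(0.01, 0.02, 0.03, 0.04) with m = 4 -> all q = 0.04."""
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        m = len(p)
        ranks = np.empty(m, int)
        ranks[order] = np.arange(1, m + 1)
        assert (q >= p * 1.0 / m - 1e-12).all()
        assert (q <= 1.0).all()


class TestExactTest:
    def test_symmetric_split_p_is_one(self):
        """Equal group sizes and a symmetric split sit at the conditional
        mode, so the two-sided p is 1."""
        counts = frame(np.full((5, 4), 50.0))
        lab = labels_for(counts.columns, 2)
        res = exact_test_de(counts, lab, dispersion=0.1)
        assert np.allclose(res["p"], 1.0)

    def test_null_type_one_error(self):
        """5000-gene NB null: rejection rate at alpha = 0.05 within
        0.05 +/- 0.01 and p-values approximately uniform (KS < 0.02)."""
        p = SimulationParams(n_genes=5000, prop_de=0.0, cv_wild=0.0,
                             nb_dispersion=0.1, n_modules=0, prop_swept=0.0,
                             lib_size_range=(5e5, 1e6), seed=11)
        counts, labels, _ = simulate_counts(p)
        res = exact_test_de(counts, labels)
        rate = (res["p"] <= 0.05).mean()
        assert 0.04 <= rate <= 0.06
        from scipy.stats import ks_1samp, uniform
        ks = ks_1samp(res["p"], uniform.cdf)
        assert ks.statistic < 0.02

    def test_planted_de_recall_and_sign(self):
        """|lfc| = 2 at 20 accessions, phi = 0.1: recall > 0.8 at FDR 0.01,
        and crop-downregulated genes get positive logFC."""
        p = SimulationParams(n_genes=2000, prop_de=0.05, lfc_magnitude=2.0,
                             cv_wild=0.0, nb_dispersion=0.1, n_modules=0,
                             prop_swept=0.0, seed=12)
        counts, labels, ledger = simulate_counts(p)
        res = exact_test_de(counts, labels, fdr=0.01)
        de_true = ledger.set_index("gene_id")["is_de"]
        assert res.loc[de_true[de_true].index, "de"].mean() > 0.8
        down = ledger.set_index("gene_id")["true_lfc"] > 0
        called = res["de"] & de_true
        sign_ok = (np.sign(res.loc[called[called].index, "logfc"])
                   == np.sign(ledger.set_index("gene_id").loc[called[called].index, "true_lfc"]))
        assert sign_ok.mean() >= 0.99
        assert down.loc[called[called].index].mean() > 0.5  # down-biased world


class TestCV:
    def test_known_values(self):
        counts = frame([[10, 10, 10, 10], [1, 2, 3, 600]])
        lab = labels_for(counts.columns, 3)
        # bypass normalization effects: equal libraries via identity factors
        cv = expression_cv(counts, lab, tmm=pd.Series(1.0, index=counts.columns),
                           lib_sizes=pd.Series(1e6, index=counts.columns))
        assert cv.loc["g0", "cv_wild"] == pytest.approx(0.0)
        assert cv.loc["g1", "cv_wild"] == pytest.approx(0.5)  # (1,2,3): sd 1, mean 2

    def test_zero_mean_gene_undefined(self):
        counts = frame([[0, 0, 0, 0], [5, 5, 5, 5]])
        lab = labels_for(counts.columns, 2)
        cv = expression_cv(counts, lab)
        assert np.isnan(cv.loc["g0", "cv_wild"])

    def test_crop_variability_shrink_recovered(self):
        """The generator's crop pool keeps ~84% of wild expression
        variability at the default shrink."""
        p = SimulationParams(n_genes=3000, seed=3, n_modules=0, prop_de=0.0,
                             prop_swept=0.0)
        counts, labels, _ = simulate_counts(p)
        cv = expression_cv(counts, labels)
        assert cv["cv_crop"].mean() / cv["cv_wild"].mean() == pytest.approx(0.84, abs=0.03)


class TestPCA:
    def test_pool_separation_and_variance(self, default_world):
        counts, labels = default_world["counts"], default_world["labels"]
        coords, var = expression_pca(counts)
        wild = (labels.reindex(coords.index) == "wild").to_numpy()
        pc1 = coords["PC1"].to_numpy()
        assert pc1[wild].max() < pc1[~wild].min() or pc1[wild].min() > pc1[~wild].max()
        assert var.sum() <= 1.0 + 1e-12

    def test_duplicate_sample_identical_coordinates(self):
        rng = np.random.default_rng(8)
        counts = frame(rng.poisson(100, size=(100, 6)))
        counts["s5"] = counts["s4"]
        coords, _ = expression_pca(counts)
        assert np.allclose(coords.loc["s4"], coords.loc["s5"], atol=1e-9)
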