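"""Size factors, dispersion estimation, the exact test and contrast tables."""

import numpy as np
import pandas as pd
import pytest

from eleanor_scan import diffexpr
from eleanor_scan.diffexpr import (
    ContrastError,
    estimate_dispersion,
    estimate_size_factors,
    nb_exact_test,
)
from eleanor_scan.synthetic_data import simulate_count_matrix

import oracles


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 10, 20], "s2": [5, 10, 20]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_splits_symmetrically(self):
        counts = pd.DataFrame({"s1": [5, 10, 20], "s2": [10, 20, 40]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_looped_definition_on_random_matrix(self):
        rng = np.random.default_rng(23)
        mat = rng.negative_binomial(5, 0.3, size=(300, 4)) + 1
        sf = estimate_size_factors(pd.DataFrame(mat))
        oracle = oracles.size_factors_by_definition(mat.tolist())
        assert np.allclose(sf.to_numpy(), oracle, atol=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(4)
        mat = rng.poisson([20, 60, 10], size=(200, 3)) + 1
        sf = estimate_size_factors(pd.DataFrame(mat))
        assert np.isclose(np.exp(np.log(sf).mean()), 1.0)

    def test_fallback_to_library_size_without_allpositive_row(self, caplog):
        counts = pd.DataFrame({"s1": [0, 10], "s2": [10, 0]})
        with caplog.at_level("WARNING"):
            sf = estimate_size_factors(counts)
        assert "library-size" in caplog.text
        assert np.allclose(sf, [1.0, 1.0])


class TestDispersion:
    def sf(self, names):
        return pd.Series(1.0, index=names)

    def test_constant_counts_floor(self):
        counts = pd.DataFrame({"s1": [7, 9], "s2": [7, 9], "s3": [7, 9]})
        model = estimate_dispersion(counts, self.sf(counts.columns),
                                    mode="blind")
        assert (model.alpha == model.floor).all()

    def test_poisson_data_floors_median_blind_alpha(self):
        counts = simulate_count_matrix(1000, mean=40.0, alpha=0.0,
                                       n_samples=4, seed=11)
        model = estimate_dispersion(counts, self.sf(counts.columns),
                                    mode="blind")
        assert np.median(model.alpha) <= 0.01

    def test_pooled_recovers_planted_alpha(self):
        """NB alpha = 0.2, 5 replicates per condition, 2,000 features:
        the median pooled estimate lands in [0.1, 0.3]."""
        rng = np.random.default_rng(31)
        r = 1 / 0.2
        mu = 50.0
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(2000, 10)),
            columns=[f"s{i}" for i in range(10)],
        )
        conds = ["x"] * 5 + ["y"] * 5
        model = estimate_dispersion(counts, self.sf(counts.columns),
                                    conditions=conds, mode="pooled")
        assert 0.1 <= np.median(model.alpha) <= 0.3

    def test_pooled_requires_replicates(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]})
        with pytest.raises(ValueError, match="2 samples per condition"):
            estimate_dispersion(counts, self.sf(counts.columns),
                                conditions=["x", "y"], mode="pooled")

    def test_common_recovers_alpha_in_three_sample_design(self):
        counts = simulate_count_matrix(4000, mean=30.0, alpha=0.1,
                                       n_samples=3, seed=12, mean_cv=0.4)
        model = estimate_dispersion(counts, self.sf(counts.columns),
                                    mode="common")
        shared = model.alpha[0]
        assert (model.alpha == shared).all()
        assert 0.05 <= shared <= 0.2

    def test_common_ignores_up_then_down_outliers(self):
        """Features 4x up in the middle sample do not inflate the common
        estimate: their first/last samples still form a null-like pair."""
        rng = np.random.default_rng(13)
        n, mu, alpha = 4000, 30.0, 0.05
        r = 1 / alpha
        mid = np.full(n, mu)
        mid[:1500] *= 4  # 37.5% differential, up-then-down
        cols = {}
        for j, m in enumerate([np.full(n, mu), mid, np.full(n, mu)]):
            cols[f"s{j}"] = rng.negative_binomial(r, r / (r + m))
        counts = pd.DataFrame(cols)
        model = estimate_dispersion(counts, self.sf(counts.columns),
                                    mode="common")
        assert model.alpha[0] < 2.5 * alpha


class TestExactTest:
    def test_zero_total_is_one(self):
        assert nb_exact_test(0, 0, 1.0, 1.0, 0.1) == 1.0

    def test_balanced_split_is_near_one(self):
        for k in (1, 7, 40):
            assert nb_exact_test(k, k, 1.0, 1.0, 0.1) >= 0.99

    def test_more_extreme_splits_have_smaller_p(self):
        N = 60
        ps = [nb_exact_test(a, N - a, 1.0, 1.0, 0.1) for a in range(N + 1)]
        for a in range(N // 2):
            assert ps[a] <= ps[a + 1] + 1e-12
        for a in range(N // 2, N):
            assert ps[a + 1] <= ps[a] + 1e-12

    @pytest.mark.parametrize("alpha", [1e-8, 0.01, 0.5])
    def test_matches_enumeration_oracle_random_spots(self, alpha):
        rng = np.random.default_rng(41)
        for _ in range(60):
            ka, kb = int(rng.integers(0, 120)), int(rng.integers(0, 120))
            sa, sb = float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2))
            p = nb_exact_test(ka, kb, sa, sb, alpha)
            assert abs(p - oracles.exact_test_pvalue(ka, kb, sa, sb,
                                                     alpha)) < 1e-9

    def test_multi_sample_counts_sum_within_conditions(self):
        p1 = nb_exact_test([3, 4], [10, 12], [1.0, 1.0], [1.0, 1.0], 0.05)
        p2 = nb_exact_test(7, 22, 2.0, 2.0, 0.05)
        assert p1 == p2

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(-1, 5, 1.0, 1.0, 0.1)


class TestDiffTable:
    def make(self, mat, conds):
        counts = pd.DataFrame(mat, columns=[f"s{j}" for j in
                                            range(len(conds))])
        sheet = pd.DataFrame({"sample": counts.columns, "condition": conds})
        return counts, sheet

    def test_all_zero_features_dropped(self):
        counts, sheet = self.make([[0, 0], [5, 9]], ["a", "b"])
        res = diffexpr.diff_table(counts, sheet, ("a", "b"))
        assert list(res.index) == [1]

    def test_unknown_condition_rejected(self):
        counts, sheet = self.make([[5, 9]], ["a", "b"])
        with pytest.raises(ContrastError):
            diffexpr.diff_table(counts, sheet, ("a", "zzz"))

    def test_boundary_log2fc_is_not_called(self):
        """log2FC exactly at the threshold stays ns: the gate is strict."""
        # normalised means 10 and 20.5 with pseudocount 0.5:
        # log2(21 / 10.5) = 1.0 exactly
        counts, sheet = self.make([[10, 41]], ["a", "b"])
        sf = pd.Series([1.0, 2.0], index=["s0", "s1"])
        res = diffexpr.diff_table(
            counts, sheet, ("a", "b"), size_factors=sf,
            dispersion=diffexpr.DispersionModel(np.array([1e-8]), "blind"),
            pseudocount=0.5,
        )
        assert np.isclose(res["log2fc"].iloc[0], 1.0)
        assert res["label"].iloc[0] == "ns"

    def test_planted_up_windows_labelled_up(self):
        """20 windows planted at +2 log2FC among 2,000 nulls at high depth:
        at least 18 are labelled up and no null window is."""
        rng = np.random.default_rng(29)
        alpha, mu = 0.02, 80.0
        r = 1 / alpha
        n = 2020
        mu_b = np.full(n, mu)
        mu_b[:20] *= 4
        mat = np.column_stack([
            rng.negative_binomial(r, r / (r + mu), size=n),
            rng.negative_binomial(r, r / (r + mu_b)),
        ])
        counts, sheet = self.make(mat, ["a", "b"])
        sf = pd.Series([1.0, 1.0], index=["s0", "s1"])
        res = diffexpr.diff_table(counts, sheet, ("a", "b"), size_factors=sf,
                                  dispersion_mode="common")
        up = res["label"] == "up"
        assert up.iloc[:20].sum() >= 18
        # a single-pair contrast lets ~0.3% of nulls through the gate
        assert up.iloc[20:].mean() <= 0.01

    def test_normalised_means_and_lfc_invariant_to_sample_scaling(self):
        rng = np.random.default_rng(7)
        mat = rng.negative_binomial(10, 1 / 3, size=(100, 2))
        counts, sheet = self.make(mat, ["a", "b"])
        sf1 = pd.Series([1.0, 1.0], index=["s0", "s1"])
        res1 = diffexpr.diff_table(counts, sheet, ("a", "b"),
                                   size_factors=sf1, dispersion_mode="blind")
        scaled = counts.copy()
        scaled["s1"] = scaled["s1"] * 3
        sf2 = pd.Series([1.0, 3.0], index=["s0", "s1"])
        res2 = diffexpr.diff_table(scaled, sheet, ("a", "b"),
                                   size_factors=sf2, dispersion_mode="blind")
        assert np.allclose(res1["log2fc"], res2["log2fc"])
        assert np.allclose(res1["mean_a"], res2["mean_a"])
        assert np.allclose(res1["mean_b"], res2["mean_b"])

    def test_labels_follow_threshold_invariant(self):
        rng = np.random.default_rng(2)
        mat = rng.poisson(25, size=(300, 2))
        mat[:40, 1] *= 5
        counts, sheet = self.make(mat, ["a", "b"])
        res = diffexpr.diff_table(counts, sheet, ("a", "b"),
                                  dispersion_mode="common")
        up = (res["log2fc"] > 1.0) & (res["pvalue"] < 0.01)
        down = (res["log2fc"] < -1.0) & (res["pvalue"] < 0.01)
        assert ((res["label"] == "up") == up).all()
        assert ((res["label"] == "down") == down).all()
        assert res["pvalue"].between(0, 1).all()
        assert res["padj"].between(0, 1).all()
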