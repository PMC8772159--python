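"""CCA with ridge + permutation inference, regularized MANOVA, Table battery."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from breathdisc.io import ConfigurationError, LUNG_FUNCTION_COLUMNS, ValidationError
from breathdisc import stats as st
from breathdisc.simulate import SimulationConfig, generate_clinical, generate_truth


class TestCcaFirst:
    def test_identical_single_columns_give_unit_correlation(self):
        x = np.abs(np.random.default_rng(0).standard_normal(50)) + 0.1
        res = st.cca_first(x[:, None], x[:, None].copy())
        assert res.rho1 == pytest.approx(1.0, abs=1e-9)

    def test_latent_model_matches_closed_form(self):
        # X = 2 cols of z + noise, Y = 2 cols of z + noise, var(z)=1:
        # corr of the two block means is 1/(1+1/2) = 2/3
        rng = np.random.default_rng(0)
        n = 500
        z = rng.standard_normal(n)
        X = np.column_stack([z + rng.standard_normal(n) for _ in range(2)])
        Y = np.column_stack([z + rng.standard_normal(n) for _ in range(2)])
        res = st.cca_first(X, Y, log=False)
        assert res.rho1 == pytest.approx(2 / 3, abs=0.07)

    def test_independent_noise_stays_weak(self):
        weak, insignificant = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((500, 10))
            Y = rng.standard_normal((500, 8))
            rho = st.cca_first(X, Y, log=False).rho1
            weak += rho < 0.35
            if seed < 5:  # permutation p on a subset to keep runtime sane
                p = st.cca_permutation_p(X, Y, B=99, seed=seed, log=False)
                insignificant += p > 0.05
        assert weak >= 18
        assert insignificant >= 4

    def test_constant_column_named_in_error(self):
        X = np.ones((30, 2))
        X[:, 0] = np.arange(30)
        with pytest.raises(ValidationError, match="constant column"):
            st.cca_first(X, np.random.rand(30, 2))

    def test_variates_have_unit_variance(self):
        rng = np.random.default_rng(1)
        res = st.cca_first(np.abs(rng.random((60, 4))), np.abs(rng.random((60, 3))))
        assert np.var(res.x_variates, ddof=1) == pytest.approx(1.0, rel=1e-6)
        assert np.var(res.y_variates, ddof=1) == pytest.approx(1.0, rel=1e-6)

    def test_rho_invariant_to_affine_rescaling_of_columns(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 3))
        Y = rng.standard_normal((80, 2))
        base = st.cca_first(X, Y, log=False).rho1
        X2 = X.copy()
        X2[:, 1] = 7.5 * X2[:, 1] - 3.0
        Y2 = Y.copy()
        Y2[:, 0] = 0.1 * Y2[:, 0] + 40.0
        assert st.cca_first(X2, Y2, log=False).rho1 == pytest.approx(base, abs=1e-8)


class TestCcaPermutation:
    def test_extreme_case_floor(self):
        rng = np.random.default_rng(3)
        x = np.abs(rng.standard_normal((60, 3)))
        assert st.cca_permutation_p(x, x.copy(), B=999, seed=0) == pytest.approx(1 / 1000)

    def test_b_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            st.cca_permutation_p(np.random.rand(20, 2), np.random.rand(20, 2), B=0)

    def test_null_pvalues_uniform(self):
        # calibration: p-values under independence pass a KS test against U(0,1)
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            X = rng.standard_normal((40, 2))
            Y = rng.standard_normal((40, 2))
            pvals.append(st.cca_permutation_p(X, Y, B=99, seed=seed, log=False))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestSubsetSelection:
    def _patient_blocks(self, seed, coupling=0.7):
        cfg = SimulationConfig(n_per_group=(10, 40, 40), n_compounds=60,
                               clinical_coupling=coupling, seed=seed)
        truth = generate_truth(cfg)
        clin = generate_clinical(truth)
        pat = np.asarray(clin["group"] != "control")
        idx = truth.disc_sets["A_vs_B"]["indices"]
        X = truth.abundances[pat][:, idx]
        Y = clin.loc[pat, list(LUNG_FUNCTION_COLUMNS)].to_numpy(float)
        return X, Y

    def test_coupled_columns_recovered(self):
        hits = 0
        for seed in range(5):
            X, Y = self._patient_blocks(seed)
            res = st.cca_subset_select(X, Y, list(LUNG_FUNCTION_COLUMNS),
                                       B_final=199, seed=seed)
            hits += sorted(res.selected_columns) == ["SixMWD", "TLC"]
        assert hits >= 3

    def test_null_coupling_selects_at_most_one_insignificant_column(self):
        X, Y = self._patient_blocks(7, coupling=0.0)
        res = st.cca_subset_select(X, Y, list(LUNG_FUNCTION_COLUMNS),
                                   B_final=199, seed=7)
        assert len(res.selected_columns) <= 1
        assert res.p_value > 0.05

    def test_max_params_one_prefers_a_coupled_column(self):
        X, Y = self._patient_blocks(3)
        res = st.cca_subset_select(X, Y, list(LUNG_FUNCTION_COLUMNS),
                                   max_params=1, B_final=199, seed=3)
        assert len(res.selected_columns) == 1
        assert res.selected_columns[0] in ("TLC", "SixMWD")


class TestRmanova:
    def test_saturated_effect_hits_the_permutation_floor(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 8))
        fac = np.array(["a"] * 30 + ["b"] * 30)
        X[fac == "b"] += 2.0
        res = st.rmanova_confounder(X, fac, B=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValidationError):
            st.rmanova_confounder(np.random.rand(20, 3), np.array(["a"] * 20))

    def test_continuous_factor_dichotomized(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 4))
        age = rng.uniform(40, 80, size=40)
        res = st.rmanova_confounder(X, age, B=99, seed=1, factor_name="age")
        assert res.n_levels == 2
        assert 1 / 100 <= res.p_value <= 1.0

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            rng = np.random.default_rng(20_000 + rep)
            X = rng.standard_normal((40, 6))
            fac = np.array(["a", "b"])[rng.integers(0, 2, size=40)]
            if np.unique(fac).size < 2:
                continue
            res = st.rmanova_confounder(X, fac, B=99, seed=rep)
            rejections += res.p_value < 0.05
        assert abs(rejections / n_reps - 0.05) < 0.03

    def test_matches_hotelling_ordering_on_small_instances(self):
        # with gamma small and p << n, the shrinkage-Wilks statistic should
        # order group separations like Hotelling's T^2
        rng = np.random.default_rng(6)
        stats_w, stats_t = [], []
        for shift in (0.0, 0.5, 1.0, 2.0):
            X = rng.standard_normal((80, 3))
            fac = np.array(["a"] * 40 + ["b"] * 40)
            X[fac == "b"] += shift
            res = st.rmanova_confounder(X, fac, B=1, seed=0)
            d = X[:40].mean(0) - X[40:].mean(0)
            S = (np.cov(X[:40].T) + np.cov(X[40:].T)) / 2
            t2 = d @ np.linalg.solve(S, d)
            stats_w.append(-res.statistic)  # small Wilks = big effect
            stats_t.append(t2)
        assert sps.spearmanr(stats_w, stats_t).statistic == 1.0


class TestUnivariateTable:
    def test_identical_groups_give_null_result(self):
        df = pd.DataFrame({"v": np.r_[np.arange(10.0), np.arange(10.0)]})
        out = st.univariate_table(df, ["a"] * 10 + ["b"] * 10)
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_bh_adjustment_matches_hand_computed_step_up(self):
        rng = np.random.default_rng(7)
        # build variables whose raw p-values we then feed through the battery
        df = pd.DataFrame({f"v{i}": rng.standard_normal(40) for i in range(5)})
        out = st.univariate_table(df, ["a"] * 20 + ["b"] * 20)
        # independent check of the step-up rule on the battery's raw p-values
        p = out["p_raw"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        stepped = np.minimum.accumulate((p[order] * m / (np.arange(m) + 1))[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(out["p_fdr"].to_numpy(), expect, rtol=1e-12)

    def test_hand_example_of_step_up_rule(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.001, 0.01, 0.02, 0.03, 0.5], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.005, 0.025, 1 / 30, 0.0375, 0.5], rtol=1e-6)

    def test_zero_variance_variable_excluded(self):
        df = pd.DataFrame({"flat": np.ones(20), "ok": np.random.default_rng(8).random(20)})
        out = st.univariate_table(df, ["a"] * 10 + ["b"] * 10)
        assert bool(out.loc[out["variable"] == "flat", "excluded"].iloc[0])
        assert not bool(out.loc[out["variable"] == "ok", "excluded"].iloc[0])

    def test_lilliefors_rejection_rate_calibrated(self):
        from statsmodels.stats.diagnostic import lilliefors
        rng = np.random.default_rng(9)
        rejections = sum(
            lilliefors(rng.standard_normal(100), dist="norm")[1] < 0.05
            for _ in range(1000)
        )
        assert abs(rejections / 1000 - 0.05) < 0.02
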