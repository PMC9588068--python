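import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pitchcomp.stats import (
    correlation_power,
    correlation_test,
    paired_t_test,
    r_density,
    repeated_anova,
    stepwise_select,
    tukey_kramer,
)


class TestCorrelationTest:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, n = correlation_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_closed_form_p(self):
        # r = 0.5, n = 10 -> t with 8 df -> p ~ 0.1411
        rng = np.random.default_rng(0)
        # construct data with exactly r = 0.5
        x = np.arange(10.0)
        y = rng.standard_normal(10)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # orthogonalize
        xs = (x - x.mean()) / x.std()
        ys = y / y.std()
        target = 0.5
        y_mix = target * xs + np.sqrt(1 - target**2) * ys
        r, p, n = correlation_test(xs, y_mix)
        assert r == pytest.approx(0.5, abs=1e-12)
        assert p == pytest.approx(0.1411, abs=2e-4)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10)
        y = 0.6 * x + rng.standard_normal(10)
        r, p, _ = correlation_test(x, y)
        perm = sps.permutation_test(
            (x, y), lambda a, b: sps.pearsonr(a, b)[0],
            permutation_type="pairings", n_resamples=20000,
            alternative="two-sided", random_state=1,
        )
        assert p == pytest.approx(perm.pvalue, abs=0.02)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 4000
        for _ in range(n_sim):
            x = rng.standard_normal(38)
            y = rng.standard_normal(38)
            _, p, _ = correlation_test(x, y)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.01)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlation_test(np.ones(5), np.arange(5.0))


class TestPairedT:
    def test_identical_inputs(self):
        t, df, p = paired_t_test(np.arange(5.0), np.arange(5.0))
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_constant_nonzero_difference_overflows(self):
        t, df, p = paired_t_test(np.arange(4.0) + 1, np.arange(4.0))
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_power_matches_noncentral_t(self):
        # shift of 0.5 SD at n=38: power from the noncentral-t closed form
        rng = np.random.default_rng(5)
        n, shift = 38, 0.5
        n_sim = 4000
        rejections = 0
        for _ in range(n_sim):
            d = rng.standard_normal(n) + shift
            t, df, p = paired_t_test(d, np.zeros(n))
            rejections += p < 0.05
        nc = shift * np.sqrt(n)
        tc = sps.t.ppf(0.975, n - 1)
        power = sps.nct.sf(tc, n - 1, nc) + sps.nct.cdf(-tc, n - 1, nc)
        assert rejections / n_sim == pytest.approx(power, abs=0.02)

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        t, df, p = paired_t_test(a, b)
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestRepeatedAnova:
    def test_identical_columns_f_zero(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 3))
        F, df1, df2, p = repeated_anova(X)
        assert F == 0.0 and p == 1.0

    def test_dof_for_38_subjects_3_conditions(self):
        rng = np.random.default_rng(0)
        F, df1, df2, p = repeated_anova(rng.standard_normal((38, 3)))
        assert (df1, df2) == (2, 74)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            repeated_anova(rng.standard_normal((38, 3)))[3] < 0.05 for _ in range(4000)
        )
        assert rejections / 4000 == pytest.approx(0.05, abs=0.01)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        X = rng.standard_normal((12, 4)) + np.array([0.0, 0.3, 0.1, -0.2])
        F, df1, df2, p = repeated_anova(X)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 4),
                "cond": np.tile(np.arange(4), 12),
                "y": X.ravel(),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject", correction=False)
        assert F == pytest.approx(float(ref["F"][0]))
        assert p == pytest.approx(float(ref["p_unc"][0]))

    def test_missing_cells_raise(self):
        X = np.ones((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            repeated_anova(X)


class TestTukeyKramer:
    def test_identical_columns_p_one(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 3)) + np.random.default_rng(0).normal(0, 1, (10, 3))
        X[:, 1] = X[:, 0]
        out = tukey_kramer(np.column_stack([X[:, 0], X[:, 0], X[:, 0]]) )
        assert (out["p_adj"] >= 0.999).all()

    def test_shifted_column_detected(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        X[:, 2] += 5.0  # 5 SDs
        out = tukey_kramer(X).set_index(["cond_i", "cond_j"])
        assert out.loc[(0, 2), "p_adj"] < 0.001
        assert out.loc[(1, 2), "p_adj"] < 0.001
        assert out.loc[(0, 1), "p_adj"] > 0.5

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((15, 3))
        out = tukey_kramer(X)
        n = X.shape[0]
        grand = X.mean()
        ss_err = ((X - grand) ** 2).sum() - n * ((X.mean(0) - grand) ** 2).sum() \
            - X.shape[1] * ((X.mean(1) - grand) ** 2).sum()
        mse = ss_err / ((X.shape[1] - 1) * (n - 1))
        for _, row in out.iterrows():
            i, j = int(row["cond_i"]), int(row["cond_j"])
            t = abs(X[:, i].mean() - X[:, j].mean()) / np.sqrt(2 * mse / n)
            p_unadj = 2 * sps.t.sf(t, (X.shape[1] - 1) * (n - 1))
            assert row["p_adj"] >= p_unadj - 1e-12


class TestStepwise:
    def make_predictors(self, rng, n=38):
        return pd.DataFrame(
            {
                "var_slow": rng.normal(13, 3.7, n),
                "var_fast": rng.normal(3.5, 1.2, n),
                "threshold": rng.normal(55, 17, n),
                "accuracy": rng.normal(14, 11, n),
                "rel_amplitude": rng.normal(0, 3, n),
                "gender": rng.integers(0, 2, n).astype(float),
            }
        )

    def test_single_true_predictor_selected(self):
        rng = np.random.default_rng(0)
        X = self.make_predictors(rng)
        y = 3 * X["var_slow"] + rng.normal(0, 0.5, len(X))
        res = stepwise_select(y, X)
        assert res.selected == ["var_slow"]
        assert res.adj_r_squared > 0.95

    def test_two_true_predictors_selected(self):
        rng = np.random.default_rng(1)
        X = self.make_predictors(rng)
        y = X["var_slow"] + 5 * X["gender"] + rng.normal(0, 0.5, len(X))
        res = stepwise_select(y, X)
        assert {"var_slow", "gender"} <= set(res.selected)

    def test_pure_noise_mostly_empty(self):
        # with six candidates at p-enter 0.05 the null entry rate is
        # ~1 - 0.95**6 ~ 26%, so expect an empty model roughly 3/4 of the time
        rng = np.random.default_rng(2)
        empty = 0
        n_rep = 60
        for _ in range(n_rep):
            X = self.make_predictors(rng)
            y = rng.standard_normal(len(X))
            empty += len(stepwise_select(y, X).selected) == 0
        assert empty / n_rep > 0.6

    def test_collinear_predictor_dropped(self):
        rng = np.random.default_rng(3)
        X = self.make_predictors(rng)
        X["dup"] = 2 * X["var_slow"]
        y = X["var_slow"] + rng.normal(0, 0.5, len(X))
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_select(y, X)
        assert "dup" in res.dropped_collinear


class TestCorrelationPower:
    def test_reference_exact_value(self):
        assert correlation_power(38, 0.37, 0.05) == pytest.approx(0.644, abs=0.005)

    def test_fisher_z_is_lower(self):
        approx = correlation_power(38, 0.37, 0.05, method="fisher")
        assert approx == pytest.approx(0.632, abs=0.005)

    def test_null_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.10):
            assert correlation_power(38, 0.0, alpha) == pytest.approx(alpha, abs=1e-6)

    def test_large_n_limit(self):
        assert correlation_power(5000, 0.37, 0.05) > 0.9999

    def test_density_integrates_to_one(self):
        from scipy import integrate
        total, _ = integrate.quad(r_density, -1 + 1e-9, 1 - 1e-9, args=(0.37, 38))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            correlation_power(3, 0.3, 0.05)
        with pytest.raises(ValueError):
            correlation_power(38, 1.2, 0.05)
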