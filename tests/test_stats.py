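import numpy as np
import pandas as pd
import pytest
from scipy import stats as scs

from swapet.stats import (
    SlowWaveAmyloidModel,
    backward_eliminate,
    correlate,
    effect_size_from_ci,
    fit_ols,
    paired_compare,
    standardize,
)


def _brute_ols(X, y):
    """Normal-equations reference solver with classical covariance."""
    Xc = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
    resid = y - Xc @ beta
    dof = len(y) - Xc.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(Xc.T @ Xc)
    return beta, np.sqrt(np.diag(cov))


class TestStandardize:
    def test_basic(self):
        z, sd = standardize([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1, 0, 1])
        assert sd == 1.0

    def test_mean_zero_sd_one(self, rng):
        z, _ = standardize(rng.normal(5, 3, 100))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])

    def test_coefficient_scaling_identity(self, rng):
        """β on z(x) equals β on x times SD(x) (checked against brute force)."""
        x = rng.normal(10, 4, 80)
        y = 0.5 * x + rng.normal(0, 1, 80)
        df = pd.DataFrame({"x": x, "y": y})
        raw = fit_ols(df, "y", ["x"])
        z, sd = standardize(x)
        std = fit_ols(pd.DataFrame({"x": z, "y": y}), "y", ["x"])
        assert std.params["x"] == pytest.approx(raw.params["x"] * sd, rel=1e-10)


class TestFitOLS:
    def test_exact_fit(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        res = fit_ols(df, "y", ["x"])
        assert res.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert res.rsquared == pytest.approx(1.0)

    def test_matches_bruteforce_to_1e10(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 1, 60)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        res = fit_ols(df, "y", ["a", "b", "c"])
        beta, se = _brute_ols(X, y)
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)
        assert np.allclose(res.bse.to_numpy(), se, atol=1e-10)
        # t-based CI reconstruction
        tcrit = scs.t.ppf(0.975, 60 - 4)
        assert np.allclose(res.conf_int["lower"], beta - tcrit * se, atol=1e-10)

    def test_vif_closed_form(self, rng):
        """Two predictors at r = 0.88 each have VIF 1/(1−0.88²) = 4.43."""
        n = 5000
        z = rng.standard_normal((n, 2))
        r = 0.88
        x1 = z[:, 0]
        x2 = r * z[:, 0] + np.sqrt(1 - r ** 2) * z[:, 1]
        # enforce the empirical correlation exactly via whitening
        X = np.column_stack([x1, x2])
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        emp = np.corrcoef(X.T)[0, 1]
        df = pd.DataFrame({"a": X[:, 0], "b": X[:, 1]})
        df["y"] = rng.normal(size=n)
        res = fit_ols(df, "y", ["a", "b"])
        expected = 1.0 / (1.0 - emp ** 2)
        assert res.vif["a"] == pytest.approx(expected, rel=1e-6)
        assert res.vif["a"] == pytest.approx(4.43, abs=0.25)
        assert res.vif["a"] <= 5.0

    def test_rank_deficient_names_alias(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x, "y": rng.normal(size=50)})
        with pytest.raises(ValueError, match="b"):
            fit_ols(df, "y", ["a", "b"])

    def test_adjusted_r2_le_r2(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=["a", "b", "c", "y"])
        res = fit_ols(df, "y", ["a", "b", "c"])
        assert res.rsquared_adj <= res.rsquared


class TestBackwardElimination:
    def _data(self, seed, n=200):
        r = np.random.default_rng(seed)
        x_strong = r.normal(size=n)
        x_noise = r.normal(size=n)
        y = 1.0 * x_strong + r.normal(0, 1, n)
        return pd.DataFrame({"strong": x_strong, "noise": x_noise, "y": y})

    def test_noise_removed_strong_retained(self):
        """The strong term always survives; the null term is removed whenever
        its p exceeds 0.1, which by the uniform null p-value distribution
        happens in ~90% of runs."""
        strong_kept = 0
        noise_removed = 0
        for seed in range(40):
            res = backward_eliminate(self._data(seed), "y", ["strong", "noise"])
            strong_kept += "strong" in res.terms
            noise_removed += "noise" not in res.terms
        assert strong_kept == 40
        assert noise_removed >= 32  # binomial(40, 0.9) well above this floor

    def test_all_forced_is_noop(self):
        df = self._data(0)
        full = fit_ols(df, "y", ["strong", "noise"])
        res = backward_eliminate(df, "y", ["strong", "noise"], forced_in=["strong", "noise"])
        assert np.allclose(res.params, full.params)
        assert res.removal_trace == []

    def test_boundary_p_retained(self, rng):
        """A term with p = 0.09 survives a 0.1 removal threshold."""
        # craft data where the weak term has p just below 0.1
        for seed in range(50):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({"a": r.normal(size=100), "b": r.normal(size=100)})
            df["y"] = 1.0 * df.a + 0.17 * df.b + r.normal(0, 1, 100)
            p = fit_ols(df, "y", ["a", "b"]).pvalues["b"]
            if 0.05 < p < 0.1:
                res = backward_eliminate(df, "y", ["a", "b"])
                assert "b" in res.terms
                return
        pytest.fail("no seed produced a boundary p-value")

    def test_threshold_extremes(self):
        df = self._data(1)
        full = backward_eliminate(df, "y", ["strong", "noise"], p_remove=1.0)
        assert set(full.terms) == {"strong", "noise"}
        only_forced = backward_eliminate(df, "y", ["strong", "noise"], forced_in=["strong"], p_remove=1e-12)
        assert only_forced.terms == ["strong"]


class TestCorrelate:
    def test_identity(self):
        x = np.linspace(0, 1, 20)
        r, p = correlate(x, x)
        assert r == pytest.approx(1.0)

    def test_rank_invariance(self, rng):
        x = rng.normal(size=50)
        y = np.exp(x)
        rs, _ = correlate(x, y, method="spearman")
        r, _ = correlate(x, y, method="pearson")
        assert rs == pytest.approx(1.0)
        assert r < 1.0

    def test_spearman_equals_pearson_on_ranks(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        rs, _ = correlate(x, y, method="spearman")
        rp, _ = correlate(scs.rankdata(x), scs.rankdata(y), method="pearson")
        assert rs == pytest.approx(rp, abs=1e-12)

    def test_log_transform(self, rng):
        x = rng.normal(size=30)
        y = np.exp(2 * x + rng.normal(0, 0.1, 30))
        r_log, _ = correlate(x, y, transform="y")
        r_raw, _ = correlate(x, y)
        assert r_log > r_raw

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


class TestPairedCompare:
    def test_reconstructs_printed_effect_sizes(self):
        """The three diagnostic-vs-titration effect sizes implied by printed
        mean differences and 95% CIs at n = 52 are 0.41, 0.61, 0.67."""
        cases = [(1.63, 0.51, 2.75, 0.41), (12.5, 6.76, 18.2, 0.61), (16.2, 9.5, 22.9, 0.67)]
        for mean, lo, hi, d in cases:
            assert effect_size_from_ci(mean, lo, hi, 52) == pytest.approx(d, abs=0.005)

    def test_matches_effect_size_from_ci(self, rng):
        """paired_compare's d agrees with the CI-reconstruction route."""
        a = rng.normal(25, 6, 52)
        b = a - rng.normal(1.6, 4.0, 52)
        c = paired_compare(a, b)
        assert effect_size_from_ci(c.mean_diff, c.ci_lower, c.ci_upper, c.n) == pytest.approx(
            c.d, rel=1e-10
        )

    def test_d_uses_correlation_adjusted_sd(self, rng):
        a = rng.normal(0, 2, 100)
        b = 0.8 * a + rng.normal(0, 1, 100)
        c = paired_compare(a, b)
        r = np.corrcoef(a, b)[0, 1]
        sa, sb = np.std(a, ddof=1), np.std(b, ddof=1)
        assert c.sd_diff == pytest.approx(np.sqrt(sa ** 2 + sb ** 2 - 2 * r * sa * sb))

    def test_identical_vectors(self, rng):
        a = rng.normal(size=20)
        with pytest.raises(ValueError):
            paired_compare(a, a)  # zero-variance differences

    def test_constant_shift_degenerate(self, rng):
        a = rng.normal(size=20)
        with pytest.raises(ValueError):
            paired_compare(a, a - 3.0)

    def test_against_scipy(self, rng):
        a = rng.normal(1, 2, 30)
        b = rng.normal(0, 2, 30)
        c = paired_compare(a, b)
        t, p = scs.ttest_rel(a, b)
        assert c.t == pytest.approx(t)
        assert c.p == pytest.approx(p)


class TestModelObjects:
    def _cohort(self, seed=0, n=200):
        from swapet.synth import SyntheticCohortSpec, synthesize_cohort

        df, params = synthesize_cohort(SyntheticCohortSpec(n=n, seed=seed))
        return df, params

    def test_fit_and_summary(self):
        df, _ = self._cohort()
        model = SlowWaveAmyloidModel(
            df, "dpib_log_yr", ["so_slope", "delta_slope"], ["age_baseline", "apoe4", "pib_positive"]
        )
        res = model.fit()
        assert set(res.terms) == {"so_slope", "delta_slope", "age_baseline", "apoe4", "pib_positive"}
        assert res.nobs == 200
        assert "so_slope" in str(res.summary())
        tidy = res.tidy()
        assert {"term", "beta", "ci_lower", "ci_upper", "p", "vif"} <= set(tidy.columns)

    def test_subgroup_refit(self):
        df, _ = self._cohort()
        model = SlowWaveAmyloidModel(
            df, "dpib_log_yr", ["so_slope"], ["age_baseline", "pib_positive"]
        )
        groups = model.fit_by_group("pib_positive")
        assert set(groups) == {0, 1}
        assert all("pib_positive" not in g.terms for g in groups.values())
        assert sum(g.nobs for g in groups.values()) == 200

    def test_predict_at_quantiles(self):
        df, _ = self._cohort()
        model = SlowWaveAmyloidModel(df, "dpib_log_yr", ["so_slope"], ["age_baseline"])
        res = model.fit()
        preds = res.predict_at_quantiles("so_slope", [0.375, 0.875])
        # positive coefficient: prediction in the upper quartile band exceeds Q2
        if res.params["so_slope"] > 0:
            assert preds[0.875] > preds[0.375]
        # brute-force check: direct linear-predictor evaluation
        q = float(res.data["so_slope"].quantile(0.375))
        x = np.array([1.0, q, res.data["age_baseline"].mean()])
        beta = res.params.to_numpy()
        assert preds[0.375] == pytest.approx(float(x @ beta), rel=1e-10)

    def test_prediction_at_means_equals_outcome_mean(self):
        df, _ = self._cohort()
        model = SlowWaveAmyloidModel(df, "dpib_log_yr", ["so_slope"], ["age_baseline"])
        res = model.fit()
        base = {t: res.data[t].mean() for t in res.terms}
        pred = res.predict(pd.DataFrame([base]))[0]
        assert pred == pytest.approx(res.data["dpib_log_yr"].mean(), rel=1e-10)

    def test_quantile_bounds_checked(self):
        df, _ = self._cohort()
        res = SlowWaveAmyloidModel(df, "dpib_log_yr", ["so_slope"]).fit()
        with pytest.raises(ValueError):
            res.predict_at_quantiles("so_slope", [1.5])
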