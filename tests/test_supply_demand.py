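"""Robust regression, nested F-test, and residual diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from taxcap import supply_demand as sd
from taxcap.errors import InputError


@pytest.fixture
def gaussian_design():
    rng = np.random.default_rng(42)
    X = np.column_stack([np.ones(200), rng.uniform(0, 5, 200), rng.uniform(0, 5, 200)])
    beta = np.array([1.0, 2.0, -0.5])
    y = X @ beta + rng.normal(0, 0.5, 200)
    return X, y, beta


class TestLog1p:
    def test_values_and_monotonicity(self):
        assert sd.log1p_transform([0.0])[0] == 0.0
        assert sd.log1p_transform([np.e - 1])[0] == pytest.approx(1.0)
        v = np.sort(np.random.default_rng(0).uniform(0, 100, 50))
        out = sd.log1p_transform(v)
        assert np.all(np.diff(out) > 0)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            sd.log1p_transform([1.0, -0.1])


class TestHuberFit:
    def test_exact_linear_data(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([np.ones(10), x])
        y = 2 + 3 * x
        fit = sd.fit_huber_rlm(X, y)
        assert fit.coefficients == pytest.approx([2.0, 3.0], abs=1e-10)
        assert np.all(fit.weights == 1.0)
        assert fit.converged

    def test_close_to_ols_on_clean_gaussian(self, gaussian_design):
        X, y, _beta = gaussian_design
        fit = sd.fit_huber_rlm(X, y)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(fit.coefficients - ols)) < 0.05

    def test_matches_statsmodels_rlm(self, gaussian_design):
        X, y, _ = gaussian_design
        y = y.copy()
        y[:10] += 8  # gross outliers so the weights actually engage
        ours = sd.fit_huber_rlm(X, y, sd.FitConfig(convergence_tol=1e-10,
                                                   max_iterations=200))
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(1.345)).fit(
            scale_est="mad", conv="coefs", tol=1e-10, maxiter=200
        )
        assert ours.coefficients == pytest.approx(ref.params, abs=1e-5)
        assert ours.scale == pytest.approx(ref.scale, rel=1e-4)
        assert ours.standard_errors == pytest.approx(ref.bse, rel=1e-3)

    def test_downweights_outliers(self, gaussian_design):
        X, y, beta = gaussian_design
        y = y.copy()
        y[:10] += 15
        fit = sd.fit_huber_rlm(X, y)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.linalg.norm(fit.coefficients - beta) < np.linalg.norm(ols - beta)
        assert fit.weights[:10].max() < 1.0

    def test_huge_tuning_constant_recovers_ols(self, gaussian_design):
        X, y, _ = gaussian_design
        fit = sd.fit_huber_rlm(X, y, sd.FitConfig(huber_t=1e12,
                                                  convergence_tol=1e-12))
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(fit.coefficients - ols)) < 1e-6

    def test_shape_and_rank_errors(self):
        with pytest.raises(InputError):
            sd.fit_huber_rlm(np.ones((3, 3)), np.ones(3))
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(InputError):
            sd.fit_huber_rlm(X, np.arange(10.0))


class TestModelComparison:
    def test_identical_models_give_zero(self, gaussian_design):
        X, y, _ = gaussian_design
        fit = sd.fit_huber_rlm(X, y)
        cmp_ = sd.compare_models_f(fit, fit, X, X)
        assert cmp_.f_statistic == 0.0 and cmp_.p_value == 1.0

    def test_ols_limit_matches_textbook_f(self):
        # hand-checkable 10-point nested comparison with all weights 1
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 10)
        y = 1 + 0.8 * x + rng.normal(0, 0.4, 10)
        X_full = np.column_stack([np.ones(10), x])
        X_red = np.ones((10, 1))
        big = sd.FitConfig(huber_t=1e12, convergence_tol=1e-12)
        full = sd.fit_huber_rlm(X_full, y, big)
        red_beta = np.array([y.mean()])
        # reduced "fit" assembled directly: intercept-only residuals
        red = sd.FitResult(
            coefficients=red_beta, standard_errors=np.zeros(1),
            p_values=np.zeros(1), scale=1.0, weights=np.ones(10),
            residuals=y - y.mean(), fitted=np.full(10, y.mean()),
            converged=True, n_iterations=1,
        )
        cmp_ = sd.compare_models_f(full, red, X_full, X_red)
        rss_full = float(np.sum(full.residuals**2))
        rss_red = float(np.sum((y - y.mean()) ** 2))
        expected_f = ((rss_red - rss_full) / 1) / (rss_full / 8)
        assert cmp_.f_statistic == pytest.approx(expected_f, rel=1e-9)
        assert cmp_.p_value == pytest.approx(stats.f.sf(expected_f, 1, 8), rel=1e-9)

    def test_detects_strong_extra_coefficient(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x1 = rng.uniform(0, 5, 60)
            x2 = rng.uniform(0, 5, 60)
            y = 1 + 0.5 * x1 + 1.2 * x2 + rng.normal(0, 0.5, 60)
            X_full = np.column_stack([np.ones(60), x1, x2])
            X_red = X_full[:, :2]
            full = sd.fit_huber_rlm(X_full, y)
            red = sd.fit_huber_rlm(X_red, y)
            if sd.compare_models_f(full, red, X_full, X_red).p_value < 0.05:
                hits += 1
        assert hits >= 95

    def test_non_nested_rejected(self, gaussian_design):
        X, y, _ = gaussian_design
        fit = sd.fit_huber_rlm(X, y)
        other = np.column_stack([np.ones(len(y)), np.arange(len(y))])
        with pytest.raises(InputError):
            sd.compare_models_f(fit, fit, X, other)


class TestDurbinWatson:
    def test_alternating_and_constant_fixtures(self):
        assert sd.durbin_watson([1, -1, 1, -1]) == pytest.approx(3.0)
        assert sd.durbin_watson([1, 1, 1, 1]) == pytest.approx(0.0)

    def test_iid_noise_near_two(self):
        resid = np.random.default_rng(123).normal(size=10_000)
        assert sd.durbin_watson(resid) == pytest.approx(2.0, abs=0.05)

    def test_range_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            dw = sd.durbin_watson(rng.normal(size=30))
            assert 0.0 <= dw <= 4.0

    def test_degenerate_inputs(self):
        with pytest.raises(InputError):
            sd.durbin_watson([1.0])
        with pytest.raises(InputError):
            sd.durbin_watson([0.0, 0.0, 0.0])


class TestBreuschPagan:
    def test_hand_computed_auxiliary_regression(self):
        # 6-point fixture: statistic = n * R^2 of e^2 on X
        X = np.column_stack([np.ones(6), np.array([1, 2, 3, 4, 5, 6.0])])
        resid = np.array([0.1, -0.2, 0.3, -0.4, 0.5, -0.6])
        e2 = resid**2
        beta, *_ = np.linalg.lstsq(X, e2, rcond=None)
        ss_res = float(np.sum((e2 - X @ beta) ** 2))
        ss_tot = float(np.sum((e2 - e2.mean()) ** 2))
        expected = 6 * (1 - ss_res / ss_tot)
        got_stat, got_p = sd.breusch_pagan(resid, X)
        assert got_stat == pytest.approx(expected, rel=1e-9)
        assert got_p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-9)

    def test_constant_squared_residuals_give_zero(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        resid = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        stat, _p = sd.breusch_pagan(resid, X)
        assert stat == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(InputError):
            sd.breusch_pagan(np.ones(4), np.ones((4, 2)))


class TestShapiroWilk:
    def test_normal_quantiles_high_w(self):
        points = stats.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, _p = sd.shapiro_wilk(points)
        assert w > 0.99

    def test_bimodal_rejected(self):
        fixture = np.concatenate([np.full(25, -5.0), np.full(25, 5.0)])
        fixture += np.random.default_rng(1).normal(0, 0.1, 50)
        _w, p = sd.shapiro_wilk(fixture)
        assert p < 0.01

    def test_constant_vector_error(self):
        with pytest.raises(InputError):
            sd.shapiro_wilk(np.ones(10))


class TestOutlierFlags:
    def make_fit(self, residuals, scale=1.0, labels=None):
        n = len(residuals)
        return sd.FitResult(
            coefficients=np.zeros(1), standard_errors=np.zeros(1),
            p_values=np.zeros(1), scale=scale, weights=np.ones(n),
            residuals=np.asarray(residuals, dtype=float), fitted=np.zeros(n),
            converged=True, n_iterations=1, row_labels=labels or [],
        )

    def test_single_spike(self):
        fit = self.make_fit([0, 0, 10, 0], labels=list("abcd"))
        assert sd.flag_outliers(fit, 3.0) == [("c", 10.0)]

    def test_infinite_threshold_empty(self):
        fit = self.make_fit([5.0, -8.0, 2.0])
        assert sd.flag_outliers(fit, float("inf")) == []

    def test_agrees_with_comprehension_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            resid = rng.normal(0, 2, 40)
            fit = self.make_fit(resid, scale=1.5)
            got = sd.flag_outliers(fit, 2.0)
            oracle = sorted(
                ((str(i), resid[i] / 1.5) for i in range(40)
                 if abs(resid[i] / 1.5) > 2.0),
                key=lambda t: abs(t[1]), reverse=True,
            )
            assert [(lbl, pytest.approx(v)) for lbl, v in oracle] == got

    def test_zero_scale_error(self):
        with pytest.raises(InputError):
            sd.flag_outliers(self.make_fit([1.0, 2.0], scale=0.0), 3.0)


class TestRatiosAndCorrelation:
    def test_ratio_values(self):
        assert sd.taxonomists_per_species(59, 1000) == 0.059
        assert sd.taxonomists_per_species(0, 10) == 0.0
        assert sd.taxonomists_per_species(35, 1000) == 0.035

    def test_ratio_ordering_scale_invariant(self):
        pairs = [(59, 1000), (35, 1000), (300, 10000)]
        base = [sd.taxonomists_per_species(a, r) for a, r in pairs]
        scaled = [sd.taxonomists_per_species(10 * a, 10 * r) for a, r in pairs]
        assert base == scaled

    def test_zero_richness_missing(self):
        assert sd.taxonomists_per_species(5, 0) is None

    def test_pearson_exact_and_hand_table(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _ = sd.pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, _ = sd.pearson_correlation(x, -2 * x + 7)
        assert r == pytest.approx(-1.0)
        y = np.array([2.0, 1, 4, 3, 7])
        # hand computation: r = cov / (sx sy)
        expected = (((x - 3) * (y - y.mean())).sum()
                    / np.sqrt(((x - 3) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        r, p = sd.pearson_correlation(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        t = expected * np.sqrt(3 / (1 - expected**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-9)

    def test_zero_variance_error(self):
        with pytest.raises(InputError):
            sd.pearson_correlation([1, 1, 1], [1, 2, 3])
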