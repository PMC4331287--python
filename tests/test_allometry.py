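"""Log-log OLS fitting, bootstrap uncertainty and prediction limits."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crocallometry.allometry import (
    BootstrapConfig,
    LogLogRegression,
    bootstrap_fit,
    fit_loglog,
    pearson_r,
    prediction_interval,
)
from crocallometry.simulate import PanelSpec, simulate_relationship
from oracles import brute_force_loglog, pearson_formula


def exact_power_law(a=0.5, b=2.0, xs=(1.0, 10.0, 100.0)):
    x = np.asarray(xs, dtype=float)
    return np.column_stack([x, 10.0**a * x**b])


class TestFit:
    def test_exact_power_law_recovered(self):
        model = fit_loglog(exact_power_law())
        assert model.intercept_ == pytest.approx(0.5, abs=1e-12)
        assert model.slope_ == pytest.approx(2.0, abs=1e-12)
        assert model.r_ == pytest.approx(1.0, abs=1e-12)
        assert model.residual_sd_ == pytest.approx(0.0, abs=1e-12)

    def test_flat_response_gives_zero_slope(self):
        model = fit_loglog([(1, 1), (10, 1), (100, 1)])
        assert model.intercept_ == pytest.approx(0.0, abs=1e-14)
        assert model.slope_ == pytest.approx(0.0, abs=1e-14)

    def test_matches_statsmodels_to_ten_digits(self):
        spec = PanelSpec(
            n=200, true_a=-5.1240, true_b=2.9221, noise_sd=0.05,
            x_range=(10, 1000), seed=123,
        )
        pairs = simulate_relationship(spec)
        model = fit_loglog(pairs)
        lx, ly = np.log10(pairs[:, 0]), np.log10(pairs[:, 1])
        ref = sm.OLS(ly, sm.add_constant(lx)).fit()
        assert model.intercept_ == pytest.approx(ref.params[0], rel=1e-10)
        assert model.slope_ == pytest.approx(ref.params[1], rel=1e-10)
        # and lands within 3 noise-scaled standard errors of the truth
        assert abs(model.slope_ - 2.9221) < 3 * ref.bse[1]
        assert abs(model.intercept_ - (-5.1240)) < 3 * ref.bse[0]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        lx = rng.uniform(0, 3, size=n)
        ly = rng.uniform(-2, 2) + rng.uniform(-3, 3) * lx
        ly = ly + rng.normal(0, 0.2, size=n)
        pairs = np.column_stack([10.0**lx, 10.0**ly])
        model = fit_loglog(pairs)
        a_ref, b_ref = brute_force_loglog(pairs)
        assert model.intercept_ == pytest.approx(a_ref, abs=1e-6)
        assert model.slope_ == pytest.approx(b_ref, abs=1e-6)

    def test_r_squared_equals_coefficient_of_determination(self, noisy_pairs):
        model = fit_loglog(noisy_pairs)
        lx = np.log10(noisy_pairs[:, 0])
        ly = np.log10(noisy_pairs[:, 1])
        fitted = model.intercept_ + model.slope_ * lx
        ss_res = np.sum((ly - fitted) ** 2)
        ss_tot = np.sum((ly - ly.mean()) ** 2)
        assert model.r_**2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_loglog([(1, 2), (3, 4)])
        with pytest.raises(ValueError, match="positive"):
            fit_loglog([(1, 2), (3, -4), (5, 6)])
        with pytest.raises(ValueError, match="constant predictor"):
            fit_loglog([(5, 1), (5, 2), (5, 3)])

    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(0, 10_000),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_rescaling_x_shifts_intercept_only(self, c, seed):
        pairs = simulate_relationship(
            PanelSpec(n=20, true_a=0.3, true_b=1.7, noise_sd=0.1, seed=seed)
        )
        base = fit_loglog(pairs)
        scaled = fit_loglog(np.column_stack([pairs[:, 0] * c, pairs[:, 1]]))
        assert scaled.slope_ == pytest.approx(base.slope_, rel=1e-9)
        assert scaled.r_ == pytest.approx(base.r_, rel=1e-9)
        assert scaled.intercept_ == pytest.approx(
            base.intercept_ - base.slope_ * np.log10(c), rel=1e-7, abs=1e-9
        )


class TestPearson:
    def test_perfect_positive_and_negative(self):
        up = exact_power_law(a=0.0, b=1.3)
        assert pearson_r(up) == pytest.approx(1.0, abs=1e-12)
        down = np.column_stack([[1, 10, 100], [10, 1, 0.1]])
        assert pearson_r(down) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula_and_scipy(self, noisy_pairs):
        r = pearson_r(noisy_pairs)
        lx, ly = np.log10(noisy_pairs[:, 0]), np.log10(noisy_pairs[:, 1])
        assert r == pytest.approx(pearson_formula(lx, ly), abs=1e-12)
        assert r == pytest.approx(stats.pearsonr(lx, ly).statistic, abs=1e-12)

    def test_constant_variate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([(1, 5), (10, 5), (100, 5)])


class TestBootstrap:
    def test_degenerate_scatter_gives_zero_width(self):
        model = bootstrap_fit(exact_power_law(), BootstrapConfig(seed=1))
        assert model.intercept_se_ == pytest.approx(0.0, abs=1e-12)
        assert model.slope_se_ == pytest.approx(0.0, abs=1e-12)
        lo, hi = model.slope_ci_
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_is_bit_identical(self, noisy_pairs):
        cfg = BootstrapConfig(n_reps=500, seed=99)
        m1 = bootstrap_fit(noisy_pairs, cfg)
        m2 = bootstrap_fit(noisy_pairs, cfg)
        assert m1.intercept_ci_ == m2.intercept_ci_
        assert m1.slope_ci_ == m2.slope_ci_
        assert np.array_equal(m1.boot_slopes_, m2.boot_slopes_)

    def test_cis_contain_point_estimates(self, noisy_pairs):
        m = bootstrap_fit(noisy_pairs, BootstrapConfig(seed=5))
        assert m.intercept_ci_[0] <= m.intercept_ <= m.intercept_ci_[1]
        assert m.slope_ci_[0] <= m.slope_ <= m.slope_ci_[1]

    def test_bootstrap_se_approaches_analytic_se(self):
        pairs = simulate_relationship(
            PanelSpec(n=200, true_a=1.0, true_b=0.8, noise_sd=0.08, seed=21)
        )
        m = bootstrap_fit(pairs, BootstrapConfig(n_reps=2000, seed=22))
        lx, ly = np.log10(pairs[:, 0]), np.log10(pairs[:, 1])
        ref = sm.OLS(ly, sm.add_constant(lx)).fit()
        assert 0.8 < m.slope_se_ / ref.bse[1] < 1.2
        assert 0.8 < m.intercept_se_ / ref.bse[0] < 1.2


class TestPrediction:
    def test_point_prediction_formula(self):
        m = LogLogRegression.from_coefficients(0.0, 1.0)
        assert m.predict_point(55.0) == pytest.approx(55.0)
        m2 = LogLogRegression.from_coefficients(0.5, 2.0)
        assert m2.predict_point(10.0) == pytest.approx(10.0**2.5)

    def test_monotonicity_in_x0(self):
        xs = np.linspace(1, 100, 50)
        up = LogLogRegression.from_coefficients(0.2, 1.5).predict(xs)
        assert np.all(np.diff(up) > 0)
        down = LogLogRegression.from_coefficients(0.2, -1.5).predict(xs)
        assert np.all(np.diff(down) < 0)

    def test_non_positive_x_rejected(self):
        m = LogLogRegression.from_coefficients(0.0, 1.0)
        with pytest.raises(ValueError):
            m.predict_point(0.0)
        with pytest.raises(ValueError):
            m.predict_point(-3.0)

    def test_zero_residual_interval_collapses(self):
        m = fit_loglog(exact_power_law())
        pred = m.prediction_interval(40.0)
        assert pred.lower == pytest.approx(pred.point)
        assert pred.upper == pytest.approx(pred.point)

    @pytest.mark.parametrize("x0", [0.5, 5.0, 50.0, 5000.0])
    def test_log_symmetry(self, noisy_pairs, x0):
        m = fit_loglog(noisy_pairs)
        pred = m.prediction_interval(x0)
        assert pred.upper / pred.point == pytest.approx(
            pred.point / pred.lower, rel=1e-12
        )

    def test_published_model_refuses_intervals(self):
        m = LogLogRegression.from_coefficients(0.4, 0.9)
        with pytest.raises(ValueError, match="published coefficients"):
            m.prediction_interval(10.0)

    def test_matches_statsmodels_prediction_interval(self, noisy_pairs):
        m = fit_loglog(noisy_pairs)
        x0 = 250.0
        pred = prediction_interval(m, x0)
        lx = np.log10(noisy_pairs[:, 0])
        ly = np.log10(noisy_pairs[:, 1])
        fit = sm.OLS(ly, sm.add_constant(lx)).fit()
        frame = fit.get_prediction(
            np.array([[1.0, np.log10(x0)]])
        ).summary_frame(alpha=0.05)
        assert np.log10(pred.lower) == pytest.approx(
            frame["obs_ci_lower"].iloc[0], abs=1e-10
        )
        assert np.log10(pred.upper) == pytest.approx(
            frame["obs_ci_upper"].iloc[0], abs=1e-10
        )

    def test_bootstrap_interval_is_log_symmetric_and_similar(self, noisy_pairs):
        m = bootstrap_fit(noisy_pairs, BootstrapConfig(n_reps=2000, seed=3))
        x0 = 100.0
        ana = m.prediction_interval(x0, method="analytic")
        boot = m.prediction_interval(x0, method="bootstrap", random_state=4)
        assert boot.upper / boot.point == pytest.approx(
            boot.point / boot.lower, rel=1e-12
        )
        assert boot.log10_halfwidth == pytest.approx(
            ana.log10_halfwidth, rel=0.35
        )

    def test_new_observation_coverage_near_nominal(self):
        """95% prediction limits catch a fresh draw ~95% of the time."""
        rng = np.random.default_rng(2024)
        true_a, true_b, sd, x0 = 0.2, 1.4, 0.08, 60.0
        hits = 0
        n_sim = 400
        for i in range(n_sim):
            pairs = simulate_relationship(
                PanelSpec(
                    n=30, true_a=true_a, true_b=true_b, noise_sd=sd,
                    x_range=(5, 500), seed=10_000 + i,
                )
            )
            m = fit_loglog(pairs)
            pred = m.prediction_interval(x0)
            new_y = 10.0 ** (
                true_a + true_b * np.log10(x0) + rng.normal(0, sd)
            )
            hits += pred.lower <= new_y <= pred.upper
        assert 0.91 <= hits / n_sim <= 0.98
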