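"""Thermal-curve estimation tests: broken-stick profiling, the Davies-type
bootstrap, exponential TMR fits, REML random intercepts, and the critical
temperature root."""

import numpy as np
import pandas as pd
import pytest

import torporflow as tf
from torporflow.thermal import ExponentialFit, ThermoregLine


def _kinked(ta, kink, plateau=15.5, slope=2.9):
    return np.where(ta < kink, plateau + slope * (kink - ta), plateau)


class TestBrokenStick:
    def test_noiseless_printed_model_kink(self):
        """The printed RMR line 104.9 - 2.9 Ta meets the 15.5 BMR plateau at
        (104.9 - 15.5)/2.9 = 30.83 deg C; the profiler must find that kink."""
        ta = np.arange(0.0, 37.0, 2.0)
        y = np.maximum(15.5, 104.9 - 2.9 * ta)
        fit = tf.fit_broken_stick(ta, y, right_slope_zero=True, n_boot=0)
        assert fit.breakpoint == pytest.approx((104.9 - 15.5) / 2.9, abs=0.05)
        plateau = fit.left_intercept + fit.left_slope * fit.breakpoint
        assert plateau == pytest.approx(15.5, abs=1e-6)
        assert fit.left_slope == pytest.approx(-2.9, abs=1e-6)

    @pytest.mark.parametrize("frac", [0.25, 0.5, 0.75])
    def test_interior_kink_consistency(self, frac):
        ta = np.linspace(0.0, 36.0, 40)
        kink = 36.0 * frac
        fit = tf.fit_broken_stick(
            ta, _kinked(ta, kink), right_slope_zero=True, n_boot=0
        )
        assert fit.breakpoint == pytest.approx(kink, abs=0.05)

    def test_free_variant_recovers_both_slopes(self):
        ta = np.linspace(5.0, 35.0, 40)
        y = np.where(ta < 20.0, 50 - 2.0 * ta, 10 + 0.5 * (ta - 20.0))
        fit = tf.fit_broken_stick(ta, y, n_boot=0)
        assert fit.breakpoint == pytest.approx(20.0, abs=0.05)
        assert fit.left_slope == pytest.approx(-2.0, abs=1e-4)
        assert fit.right_slope == pytest.approx(0.5, abs=1e-4)

    def test_segmented_rss_never_exceeds_linear(self):
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(15):
            ta = rng.uniform(0, 35, 30)
            y = rng.normal(20, 5, 30)
            try:
                fit = tf.fit_broken_stick(ta, y, n_boot=0)
            except ValueError:
                continue  # optimum pinned at the edge with <3 points per side
            assert fit.rss_segmented <= fit.rss_linear + 1e-9
            checked += 1
        assert checked >= 8

    def test_linear_null_not_rejected(self):
        rng = np.random.default_rng(8)
        ta = rng.uniform(15, 36, 36)
        y = 40.0 - 0.5 * ta + rng.normal(0, 3, 36)
        fit = tf.fit_broken_stick(ta, y, n_boot=499, seed=4)
        assert fit.linearity_pvalue > 0.05
        assert fit.rss_segmented <= fit.rss_linear

    def test_strong_kink_rejected(self):
        rng = np.random.default_rng(9)
        ta = rng.uniform(18, 36.5, 36)
        y = _kinked(ta, 29.7) + rng.normal(0, 3, 36)
        fit = tf.fit_broken_stick(ta, y, n_boot=499, seed=4)
        assert fit.linearity_pvalue <= 0.01

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="6"):
            tf.fit_broken_stick([1, 2, 3], [1, 2, 3], n_boot=0)


class TestExponentialFit:
    def test_exact_recovery_on_own_curve(self):
        ta = np.arange(2.0, 32.0, 4.0)
        fit = tf.fit_exponential(ta, 0.141 * 1.151**ta)
        assert fit.coeff_a == pytest.approx(0.141, abs=1e-6)
        assert fit.base_b == pytest.approx(1.151, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.converged

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        ta = rng.uniform(0, 30, 40)
        y = 0.2 * 1.12**ta * np.exp(rng.normal(0, 0.2, 40))
        f1 = tf.fit_exponential(ta, y)
        f2 = tf.fit_exponential(ta, 10.0 * y)
        assert f2.coeff_a == pytest.approx(10.0 * f1.coeff_a, rel=1e-9)
        assert f2.base_b == pytest.approx(f1.base_b, rel=1e-9)

    def test_constant_response_reports_no_growth(self):
        fit = tf.fit_exponential(np.arange(10.0), np.full(10, 4.0))
        assert fit.base_b == pytest.approx(1.0, abs=1e-9)
        assert fit.coeff_a == pytest.approx(4.0, abs=1e-9)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="exclude"):
            tf.fit_exponential([1, 2, 3, 4], [1.0, 2.0, -0.1, 3.0])

    def test_matches_scipy_curve_fit(self):
        from scipy.optimize import curve_fit

        rng = np.random.default_rng(6)
        ta = rng.uniform(0, 30, 60)
        y = 0.141 * 1.151**ta * np.exp(rng.normal(0, 0.25, 60))
        mine = tf.fit_exponential(ta, y)
        ref, _ = curve_fit(
            lambda x, a, b: a * b**x, ta, y, p0=[mine.coeff_a, mine.base_b]
        )
        assert mine.coeff_a == pytest.approx(ref[0], rel=1e-6)
        assert mine.base_b == pytest.approx(ref[1], rel=1e-6)


class TestRandomIntercept:
    def _data(self, seed=7, tau=2.0, sigma=1.0, n_groups=8):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(n_groups), rng.integers(3, 9, n_groups))
        x = rng.uniform(0, 10, g.size)
        u = rng.normal(0, tau, n_groups)
        y = 1.5 + 0.8 * x + u[g] + rng.normal(0, sigma, g.size)
        X = np.column_stack([np.ones(g.size), x])
        return y, X, g

    def test_lambda_zero_is_ols_exactly(self):
        y, X, g = self._data()
        fit = tf.fit_random_intercept(y, X, g, lambda_fix=0.0)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.fixed_effects[0][1] == pytest.approx(beta[0], abs=1e-10)
        assert fit.fixed_effects[1][1] == pytest.approx(beta[1], abs=1e-10)
        assert fit.tau2_id == 0.0

    def test_balanced_anova_closed_form(self):
        rng = np.random.default_rng(2)
        k, m = 6, 5
        u = rng.normal(0, 3.0, k)
        y = (u[:, None] + rng.normal(0, 1.5, (k, m))).ravel()
        g = np.repeat(np.arange(k), m)
        fit = tf.fit_random_intercept(y, np.ones((k * m, 1)), g)
        ybar = y.reshape(k, m).mean(axis=1)
        msb = m * np.sum((ybar - y.mean()) ** 2) / (k - 1)
        msw = np.sum((y.reshape(k, m) - ybar[:, None]) ** 2) / (k * (m - 1))
        assert fit.tau2_id == pytest.approx((msb - msw) / m, abs=1e-4)
        assert fit.sigma2_resid == pytest.approx(msw, abs=1e-4)

    def test_against_statsmodels_reml(self):
        import statsmodels.api as sm

        y, X, g = self._data()
        mine = tf.fit_random_intercept(y, X, g)
        ref = sm.MixedLM(y, X, groups=g).fit(reml=True)
        assert mine.fixed_effects[0][1] == pytest.approx(ref.fe_params[0], abs=1e-4)
        assert mine.fixed_effects[1][1] == pytest.approx(ref.fe_params[1], abs=1e-4)
        assert mine.tau2_id == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=1e-2)
        assert mine.sigma2_resid == pytest.approx(ref.scale, rel=1e-2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            tf.fit_random_intercept(
                np.arange(5.0), np.ones((5, 1)), np.zeros(5)
            )

    def test_slope_coverage_under_resampling(self):
        """The fixed-effect slope lands within two reported standard errors of
        the generating slope in at least 90% of replicates."""
        hits = 0
        reps = 40
        for r in range(reps):
            y, X, g = self._data(seed=100 + r, tau=5.0, sigma=3.0)
            fit = tf.fit_random_intercept(y, X, g)
            _, est, se = fit.fixed_effects[1]
            hits += abs(est - 0.8) <= 2 * se
        assert hits / reps >= 0.90


class TestThermoregLine:
    def test_shared_line_recovered_exactly(self):
        rows = []
        for bat in range(4):
            for ta in (0.5, 3.0, 6.0):
                rows.append((f"b{bat}", ta, 10.0 - 1.3 * ta))
        line = tf.estimate_thermoreg_line(
            pd.DataFrame(rows, columns=["bat_id", "ta", "vo2"])
        )
        assert line.slope == pytest.approx(1.3, abs=1e-8)
        assert line.intercept_at_0 == pytest.approx(10.0, abs=1e-8)
        assert line.tau2_id == pytest.approx(0.0, abs=1e-8)

    def test_requires_two_bats(self):
        pts = pd.DataFrame(
            {"bat_id": ["a", "a"], "ta": [0.5, 5.0], "vo2": [8.0, 2.0]}
        )
        with pytest.raises(ValueError, match="2"):
            tf.estimate_thermoreg_line(pts)

    def test_conformer_contamination_attenuates(self):
        rng = np.random.default_rng(4)
        curve = ExponentialFit(coeff_a=0.141, base_b=1.151, r2=1.0, n_points=0)
        anchor = float(curve.predict(6.7))
        rows = []
        for bat in range(6):
            for ta in (0.5, 3.0, 6.0):
                true = anchor + 1.3 * (6.7 - ta)
                if bat >= 4:  # two thermoconformers pooled in by mistake
                    true = float(curve.predict(ta))
                rows.append((f"b{bat}", ta, true + rng.normal(0, 0.1)))
        line = tf.estimate_thermoreg_line(
            pd.DataFrame(rows, columns=["bat_id", "ta", "vo2"])
        )
        assert line.slope < 1.3


class TestCriticalTa:
    def test_closed_form_example(self):
        # 10 - T = 1.2**T has its root at 6.642761797717789
        line = ThermoregLine(slope=1.0, intercept_at_0=10.0, n_points=0, n_individuals=0)
        curve = ExponentialFit(coeff_a=1.0, base_b=1.2, r2=1.0, n_points=0)
        root = tf.find_critical_ta(line, curve, bracket=(0.0, 10.0))
        assert root == pytest.approx(6.642761797717789, abs=1e-6)

    def test_grid_scan_oracle_agreement(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            t_star = rng.uniform(2.0, 12.0)
            a = rng.uniform(0.05, 0.3)
            b = rng.uniform(1.05, 1.2)
            slope = rng.uniform(0.5, 3.0)
            curve = ExponentialFit(coeff_a=a, base_b=b, r2=1.0, n_points=0)
            line = ThermoregLine(
                slope=slope,
                intercept_at_0=float(curve.predict(t_star)) + slope * t_star,
                n_points=0, n_individuals=0,
            )
            root = tf.find_critical_ta(line, curve, bracket=(0.0, 20.0))
            ts = np.arange(0.0, 20.0, 1e-4)
            oracle = ts[np.argmin(np.abs(line.predict(ts) - curve.predict(ts)))]
            assert abs(root - oracle) <= 1e-3

    def test_warmest_root_returned(self):
        # an increasing "line" crosses the exponential twice; the warmest
        # intersection is the one reported
        curve = ExponentialFit(coeff_a=0.5, base_b=1.3, r2=1.0, n_points=0)
        line = ThermoregLine(slope=-2.0, intercept_at_0=0.2, n_points=0, n_individuals=0)
        d = lambda t: line.predict(t) - curve.predict(t)
        root = tf.find_critical_ta(line, curve, bracket=(0.0, 20.0))
        ts = np.linspace(0, 20, 200001)
        dv = d(ts)
        crossings = ts[:-1][np.sign(dv[:-1]) * np.sign(dv[1:]) < 0]
        assert crossings.size >= 2
        assert root == pytest.approx(crossings.max(), abs=1e-3)

    def test_no_intersection_reports_endpoints(self):
        line = ThermoregLine(slope=1.0, intercept_at_0=0.05, n_points=0, n_individuals=0)
        curve = ExponentialFit(coeff_a=1.0, base_b=1.2, r2=1.0, n_points=0)
        with pytest.raises(ValueError, match="d\\(0.0\\)"):
            tf.find_critical_ta(line, curve, bracket=(0.0, 10.0))
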