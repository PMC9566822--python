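"""Segmented-regression interrupted time series."""

from datetime import date, timedelta

import numpy as np
import pytest

from mhpulse.its import (
    DailySeries,
    SegmentedITS,
    build_its_design,
    fit_segmented_ols,
    sensitivity_analysis,
)
from mhpulse.synthetic import generate_its_series

from _oracles import ols_normal_equations

POLICY = date(2020, 3, 24)
TRUE_BETA = (0.0528, -0.0021, -0.0214, 0.002)


def _series(y, policy=POLICY, window=15):
    start = policy - timedelta(days=window)
    dates = [start + timedelta(days=i) for i in range(len(y))]
    return DailySeries(dates, np.clip(y, 0, 1))


class TestBuildDesign:
    def test_window_15_shape_and_break(self):
        y = generate_its_series(*TRUE_BETA, 15, 15, 0.0)
        design = build_its_design(_series(y), POLICY, 15)
        assert len(design.y) == 30
        assert design.policy[:15].sum() == 0 and design.policy[15:].sum() == 15
        assert design.t[0] == 1 and design.t[-1] == 30

    def test_window_2_exhaustive_cells(self):
        y = np.array([0.1, 0.2, 0.3, 0.4])
        design = build_its_design(_series(y, window=2), POLICY, 2)
        expected_X = np.array([
            [1, 1, 0, 0],
            [1, 2, 0, 0],
            [1, 3, 1, 3],
            [1, 4, 1, 4],
        ], dtype=float)
        np.testing.assert_array_equal(design.X, expected_X)

    def test_order_invariance_of_input_pairs(self):
        y = generate_its_series(*TRUE_BETA, 15, 15, 0.005, seed=3)
        start = POLICY - timedelta(days=15)
        pairs = [(start + timedelta(days=i), float(np.clip(y[i], 0, 1)))
                 for i in range(30)]
        s1 = DailySeries.from_pairs(pairs)
        s2 = DailySeries.from_pairs(pairs[::-1])
        d1 = build_its_design(s1, POLICY, 15)
        d2 = build_its_design(s2, POLICY, 15)
        np.testing.assert_array_equal(d1.X, d2.X)
        np.testing.assert_array_equal(d1.y, d2.y)

    def test_missing_coverage_names_dates(self):
        y = np.full(10, 0.05)
        with pytest.raises(ValueError, match="missing dates"):
            build_its_design(_series(y, window=5), POLICY, 15)


class TestFit:
    def test_noiseless_exact_recovery(self):
        """Noiseless data from the planted segmented model is refit exactly."""
        y = generate_its_series(*TRUE_BETA, 15, 15, 0.0)
        fit = SegmentedITS.from_series(_series(y), POLICY, 15).fit()
        np.testing.assert_allclose(fit.params, TRUE_BETA, atol=1e-10)
        np.testing.assert_allclose(fit.fittedvalues + fit.resid, fit.fittedvalues,
                                   atol=1e-9)

    def test_constant_series(self):
        y = np.full(30, 0.04)
        fit = SegmentedITS.from_series(_series(y), POLICY, 15).fit()
        np.testing.assert_allclose(fit.params[1:], 0.0, atol=1e-12)
        assert fit.fvalue == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        """Coefficients, SEs, t, p and F match a textbook OLS implementation."""
        rng = np.random.default_rng(2)
        for seed in range(10):
            y = generate_its_series(*TRUE_BETA, 15, 15, 0.004, seed=seed)
            series = _series(y)
            design = build_its_design(series, POLICY, 15)
            fit = fit_segmented_ols(design)
            ref = ols_normal_equations(design.X, design.y)
            np.testing.assert_allclose(fit.params, ref["beta"], atol=1e-10)
            np.testing.assert_allclose(fit.bse, ref["se"], atol=1e-10)
            np.testing.assert_allclose(fit.tvalues, ref["t"], atol=1e-8)
            np.testing.assert_allclose(fit.pvalues, ref["p"], atol=1e-10)
            assert fit.fvalue == pytest.approx(ref["F"], rel=1e-8)
            assert fit.f_pvalue == pytest.approx(ref["F_p"], abs=1e-10)

    def test_date_shift_changes_only_nothing(self):
        """Shifting all dates by a constant leaves every coefficient
        unchanged (t is relative to the window, not the calendar)."""
        y = generate_its_series(*TRUE_BETA, 15, 15, 0.003, seed=9)
        f1 = SegmentedITS.from_series(_series(y), POLICY, 15).fit()
        shift = timedelta(days=100)
        s2 = DailySeries([d + shift for d in _series(y).dates], np.clip(y, 0, 1))
        f2 = SegmentedITS.from_series(s2, POLICY + shift, 15).fit()
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-12)

    def test_missing_days_interpolated_with_warning(self, caplog):
        y = generate_its_series(*TRUE_BETA, 15, 15, 0.0)
        start = POLICY - timedelta(days=15)
        pairs = [(start + timedelta(days=i), float(np.clip(y[i], 0, 1)))
                 for i in range(30) if i not in (7, 20)]
        with caplog.at_level("WARNING"):
            series = DailySeries.from_pairs(pairs)
        assert any("interpolating" in m for m in caplog.messages)
        fit = SegmentedITS.from_series(series, POLICY, 15).fit()
        # linear interpolation of a piecewise-linear signal is exact off the break
        np.testing.assert_allclose(fit.params, TRUE_BETA, atol=1e-10)

    def test_too_many_missing_refused(self):
        pairs = [(POLICY + timedelta(days=3 * i), 0.05) for i in range(10)]
        with pytest.raises(ValueError, match="refusing"):
            DailySeries.from_pairs(pairs)

    def test_newey_west_flag_changes_only_inference(self):
        y = generate_its_series(*TRUE_BETA, 15, 15, 0.004, seed=4)
        m = SegmentedITS.from_series(_series(y), POLICY, 15)
        a, b = m.fit(), m.fit(cov_type="HAC")
        np.testing.assert_allclose(a.params, b.params, atol=1e-14)
        assert not np.allclose(a.bse, b.bse)


class TestSensitivity:
    def test_noiseless_flat_step_identical_across_windows(self):
        """With no slope terms, every window recovers the same step exactly."""
        y = generate_its_series(0.05, 0.0, -0.02, 0.0, 25, 25, 0.0)
        series = _series(y, window=25)
        tab = sensitivity_analysis(series, POLICY, windows=(10, 15, 20, 25))
        np.testing.assert_allclose(tab["intercept"], 0.05, atol=1e-10)
        np.testing.assert_allclose(tab["policy"], -0.02, atol=1e-10)
        np.testing.assert_allclose(tab["time"], 0.0, atol=1e-10)
        np.testing.assert_allclose(tab["time_policy"], 0.0, atol=1e-10)

    def test_noiseless_windows_follow_reindexing_map(self):
        """Slope terms are window-invariant; intercept and step transform by
        the exact affine map induced by re-basing t = 1 at each window start
        (window w starts offset = 25 - w days later than the widest)."""
        b0, b1, d, g = TRUE_BETA
        y = generate_its_series(b0, b1, d, g, 25, 25, 0.0)
        series = _series(y, window=25)
        tab = sensitivity_analysis(series, POLICY, windows=(10, 15, 20, 25))
        for _, row in tab.iterrows():
            off = 25 - row["window_days"]
            assert row["time"] == pytest.approx(b1, abs=1e-10)
            assert row["time_policy"] == pytest.approx(g, abs=1e-10)
            assert row["intercept"] == pytest.approx(b0 + b1 * off, abs=1e-10)
            assert row["policy"] == pytest.approx(d + g * off, abs=1e-10)

    def test_single_window_equals_direct_fit(self):
        y = generate_its_series(*TRUE_BETA, 15, 15, 0.004, seed=8)
        series = _series(y)
        tab = sensitivity_analysis(series, POLICY, windows=(15,))
        fit = SegmentedITS.from_series(series, POLICY, 15).fit()
        assert tab.loc[0, "policy"] == pytest.approx(fit.level_change)
        assert tab.loc[0, "f_statistic"] == pytest.approx(fit.fvalue)


class TestStatisticalProperties:
    def test_type_one_error_rate(self):
        """Null rejection rate of the level-change test is ~5% (600 reps)."""
        rejections = 0
        n_reps = 600
        for seed in range(n_reps):
            y = generate_its_series(0.05, 0.0, 0.0, 0.0, 15, 15, 0.003, seed=seed)
            fit = SegmentedITS.from_series(_series(y), POLICY, 15).fit()
            rejections += fit.pvalues[2] < 0.05
        assert 0.025 <= rejections / n_reps <= 0.075

    def test_planted_effect_bias_small(self):
        """Step and slope changes estimated with <5% relative bias when the
        noise is no larger than the effect (300 reps)."""
        delta, gamma = -0.02, 0.002
        est_d, est_g = [], []
        for seed in range(300):
            y = generate_its_series(0.05, -0.001, delta, gamma, 15, 15, 0.003,
                                    seed=seed + 1000)
            fit = SegmentedITS.from_series(_series(y), POLICY, 15).fit()
            est_d.append(fit.level_change)
            est_g.append(fit.slope_change)
        assert abs(np.mean(est_d) - delta) < 0.05 * abs(delta)
        assert abs(np.mean(est_g) - gamma) < 0.05 * abs(gamma)
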