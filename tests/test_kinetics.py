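"""Closure-kinetics fitting: normalization, rate windows, hinge fits,
model selection, and the 1 - SSC/TSS goodness-of-fit contract."""

import numpy as np
import pytest
import scipy.optimize
import scipy.stats
from hypothesis import given, strategies as st

from woundkin import (
    ClosureSeries,
    DegenerateDataError,
    DegenerateSeriesError,
    InsufficientDataError,
    InvalidInputError,
    MissingTimepointError,
    fit_biphasic,
    fit_monophasic,
    fit_series,
    normalize_gap,
    r_squared,
    select_model,
    trim_to_closure,
    window_rate,
)
from woundkin.kinetics import candidate_breakpoints


def series(times, pct=None, area=None, cond="c", rep="r1"):
    return ClosureSeries(
        condition=cond, replicate=rep,
        times=np.asarray(times, float),
        gap_pct=None if pct is None else np.asarray(pct, float),
        gap_area=None if area is None else np.asarray(area, float),
    )


class TestNormalizeGap:
    @pytest.mark.parametrize(
        "areas, expected",
        [
            ([200, 150, 100], [100, 75, 50]),
            ([50, 50, 50], [100, 100, 100]),
            ([80, 0], [100, 0]),
        ],
    )
    def test_percent_of_initial_area(self, areas, expected):
        t = np.arange(len(areas)) * 3.0
        out = normalize_gap(series(t, area=areas))
        np.testing.assert_allclose(out.gap_pct, expected)
        assert out.gap_pct[0] == 100.0

    def test_nonpositive_initial_area_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_gap(series([0, 3], area=[0, 10]))

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(InvalidInputError):
            series([0, 3, 3], area=[10, 8, 6])


class TestTrimToClosure:
    def test_tail_after_first_subfloor_point_dropped(self):
        out = trim_to_closure(series([0, 3, 6, 9, 12], pct=[100, 50, 1, 0, 0]))
        np.testing.assert_allclose(out.gap_pct, [100, 50, 1])

    def test_unclosed_series_unchanged(self):
        s = series([0, 3, 6], pct=[100, 80, 60])
        out = trim_to_closure(s)
        np.testing.assert_allclose(out.gap_pct, s.gap_pct)

    def test_minimum_two_points_preserved(self):
        out = trim_to_closure(series([0, 3], pct=[100, 0]))
        assert out.n_points == 2

    def test_immediate_closure_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            trim_to_closure(series([0, 3], pct=[100, 0]), floor_pct=100.0)


class TestWindowRate:
    def test_table_rate_from_six_hour_decline(self):
        # 100% -> 79.78% over 6 h is a 3.37 delta-%/h decline
        s = series([0, 3, 6], pct=[100, 90, 79.78])
        assert window_rate(s, 0.0) == pytest.approx(3.37)

    def test_flat_series_rate_zero(self):
        s = series([0, 3, 6], pct=[100, 100, 100])
        assert window_rate(s, 0.0) == 0.0

    def test_constant_decline_gives_same_rate_everywhere(self):
        t = np.arange(0.0, 16.0, 2.0)
        s = series(t, pct=100.0 - t)
        for t0 in t[:-3]:
            assert window_rate(s, t0) == pytest.approx(1.0)

    def test_off_grid_time_rejected(self):
        s = series([0, 3, 6], pct=[100, 90, 80])
        with pytest.raises(MissingTimepointError):
            window_rate(s, 1.0)


class TestMonophasicFit:
    def test_exact_line_recovery(self, linear_series):
        fit = fit_monophasic(linear_series)
        assert fit.model == "monophasic"
        assert fit.k1 == pytest.approx(3.37, abs=1e-12)
        assert fit.r_squared == 1.0
        assert fit.sse == 0.0

    def test_flat_series(self):
        fit = fit_monophasic(series([0, 3, 6], pct=[100, 100, 100]))
        assert fit.k1 == pytest.approx(0.0, abs=1e-12)
        assert fit.sse == 0.0
        assert fit.r_squared == 1.0

    def test_two_point_line(self):
        fit = fit_monophasic(series([0, 6], pct=[100, 88]))
        assert fit.k1 == pytest.approx(2.0, abs=1e-12)

    def test_window_rate_matches_fitted_slope_on_linear_series(self, linear_series):
        fit = fit_monophasic(linear_series)
        for t0 in linear_series.times[:-2]:
            assert window_rate(linear_series, t0) == pytest.approx(fit.k1)


def _oracle_hinge_sse(t, y, tb):
    """Independent continuous-hinge refit via scipy.optimize (nonlinear route)."""

    def resid(params):
        a, k1, k2 = params
        pred = np.where(t <= tb, a - k1 * t, a - k1 * tb - k2 * (t - tb))
        return y - pred

    sol = scipy.optimize.least_squares(resid, x0=[y[0], 1.0, 1.0], method="lm")
    return float(np.sum(sol.fun**2))


class TestBiphasicFit:
    def test_exact_hinge_recovery(self, hinge_series):
        fit = fit_biphasic(hinge_series)
        assert fit.model == "biphasic"
        assert fit.k1 == pytest.approx(4.0, abs=1e-9)
        assert fit.k2 == pytest.approx(10.0, abs=1e-9)
        assert fit.breakpoint_h == 9.0
        assert fit.sse == 0.0
        assert fit.r_squared == 1.0

    def test_decelerating_hinge_recovered(self):
        t = np.arange(0.0, 25.0, 3.0)
        y = np.where(t <= 9.0, 100.0 - 10.0 * t, 100.0 - 90.0 - 0.5 * (t - 9.0))
        fit = fit_biphasic(series(t, pct=y))
        assert fit.k1 == pytest.approx(10.0, abs=1e-9)
        assert fit.k2 == pytest.approx(0.5, abs=1e-9)
        assert fit.breakpoint_h == 9.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_biphasic(series([0, 3, 6, 9, 12], pct=[100, 90, 80, 70, 60]))

    def test_breakpoint_has_three_points_per_side(self):
        t = np.arange(0.0, 22.0, 3.0)  # 8 points
        np.testing.assert_array_equal(candidate_breakpoints(t), [6.0, 9.0, 12.0, 15.0])

    def test_breakpoint_minimizes_sse_over_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 25.0, 3.0)
        for _ in range(50):
            k1 = rng.uniform(1, 3)
            k2 = rng.uniform(3, 6)
            tb = rng.choice([9.0, 12.0, 15.0])
            clean = np.where(t <= tb, 100 - k1 * t, 100 - k1 * tb - k2 * (t - tb))
            y = np.clip(clean + rng.normal(0, 2, t.size), 0, None)
            y[0] = 100.0
            fit = fit_biphasic(series(t, pct=y))
            oracle = {
                cand: _oracle_hinge_sse(t, y, cand) for cand in candidate_breakpoints(t)
            }
            assert fit.sse <= min(oracle.values()) + 1e-7
            assert fit.sse == pytest.approx(oracle[fit.breakpoint_h], abs=1e-7)

    def test_biphasic_sse_never_exceeds_monophasic(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 25.0, 3.0)
        for _ in range(25):
            y = np.clip(100 - rng.uniform(1, 3) * t + rng.normal(0, 3, t.size), 0, None)
            y[0] = 100.0
            s = series(t, pct=y)
            assert fit_biphasic(s).sse <= fit_monophasic(s).sse + 1e-9


class TestModelSelection:
    def test_straight_line_stays_monophasic(self, linear_series):
        mono = fit_monophasic(linear_series)
        bi = fit_biphasic(linear_series)
        sel = select_model(mono, bi, linear_series.n_points)
        assert sel.chosen.model == "monophasic"

    def test_accelerating_hinge_classified_biphasic(self, hinge_series):
        mono = fit_monophasic(hinge_series)
        bi = fit_biphasic(hinge_series)
        sel = select_model(mono, bi, hinge_series.n_points)
        assert sel.chosen.model == "biphasic"
        assert sel.p_value < 0.05

    def test_decelerating_perfect_hinge_not_classified_biphasic(self):
        t = np.arange(0.0, 25.0, 3.0)
        y = np.where(t <= 9.0, 100.0 - 10.0 * t, 10.0 - 0.5 * (t - 9.0))
        s = series(t, pct=y)
        sel = select_model(fit_monophasic(s), fit_biphasic(s), s.n_points)
        assert sel.chosen.model == "monophasic"  # k2 < k1: no acceleration

    def test_decisions_match_f_rule_arithmetic(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 25.0, 3.0)
        n = t.size
        for _ in range(100):
            k1 = rng.uniform(2, 4)
            k2 = k1 + rng.uniform(-0.5, 1.5)  # borderline acceleration
            clean = np.where(t <= 12, 100 - k1 * t, 100 - 12 * k1 - k2 * (t - 12))
            y = np.clip(clean + rng.normal(0, 1.5, n), 0, None)
            y[0] = 100.0
            s = series(t, pct=y)
            mono, bi = fit_monophasic(s), fit_biphasic(s)
            sel = select_model(mono, bi, n)
            # independent recomputation from the two SSE values
            f_ref = ((mono.sse - bi.sse) / 2) / (bi.sse / (n - 4))
            p_ref = scipy.stats.f.sf(f_ref, 2, n - 4)
            expect = "biphasic" if (p_ref < 0.05 and bi.k2 > bi.k1) else "monophasic"
            assert sel.chosen.model == expect
            assert sel.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_too_few_observations_rejected(self, hinge_series):
        mono = fit_monophasic(hinge_series)
        bi = fit_biphasic(hinge_series)
        with pytest.raises(InsufficientDataError):
            select_model(mono, bi, 4)


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([100, 70, 40], [100, 70, 40]) == 1.0

    def test_fit_at_mean_scores_zero(self):
        obs = [100.0, 70.0, 40.0]
        assert r_squared(obs, [70.0, 70.0, 70.0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_fixture(self):
        # SSC = 4 + 4 + 0 = 8; TSS about mean 76.667 = 11400/9
        assert r_squared([100, 80, 50], [98, 82, 50]) == pytest.approx(
            1.0 - 72.0 / 11400.0, abs=1e-12
        )

    def test_flat_data_with_residuals_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            r_squared([50, 50, 50], [49, 50, 51])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            r_squared([1, 2], [1, 2, 3])

    @given(
        slope=st.floats(-5, 5),
        noise_seed=st.integers(0, 10_000),
        n=st.integers(4, 12),
    )
    def test_equals_squared_pearson_for_monophasic_fit(self, slope, noise_seed, n):
        rng = np.random.default_rng(noise_seed)
        t = np.arange(n) * 3.0
        y = np.clip(100 + slope * t + rng.normal(0, 2, n), 0, None)
        if np.ptp(y) == 0 or np.ptp(t) == 0:
            return
        fit = fit_monophasic(series(t, pct=y))
        pearson = scipy.stats.pearsonr(t, y).statistic
        assert fit.r_squared == pytest.approx(pearson**2, abs=1e-9)


class TestTimeUnitInvariance:
    def test_minute_rescaling_scales_rates_by_sixty(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 25.0, 3.0)
        y = np.clip(
            np.where(t <= 12, 100 - 3 * t, 100 - 36 - 5 * (t - 12))
            + rng.normal(0, 1, t.size),
            0,
            None,
        )
        y[0] = 100.0
        s_h = series(t, pct=y)
        s_min = series(t * 60.0, pct=y)
        for fitter in (fit_monophasic, fit_biphasic):
            fh, fm = fitter(s_h), fitter(s_min)
            assert fm.k1 == pytest.approx(fh.k1 / 60.0, rel=1e-9)
            assert fm.r_squared == pytest.approx(fh.r_squared, rel=1e-9)
            if fh.k2 is not None:
                assert fm.k2 == pytest.approx(fh.k2 / 60.0, rel=1e-9)
                assert fm.breakpoint_h == pytest.approx(fh.breakpoint_h * 60.0)
        sel_h = fit_series(s_h)
        sel_m = fit_series(s_min)
        assert sel_h.chosen.model == sel_m.chosen.model


class TestFitSeries:
    def test_short_series_falls_back_to_monophasic(self):
        s = series([0, 3, 6, 9], pct=[100, 90, 80, 70])
        sel = fit_series(s)
        assert sel.chosen.model == "monophasic"
        assert sel.p_value == 1.0
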