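"""RMS, normalization, trend fitting, and subject aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfatigue.fatigue import (
    FatigueSeries,
    TrendSummary,
    aggregate_subject,
    conc_ecc_ratio,
    fit_line,
    fit_trend,
    normalize_rms,
    segment_rms,
)
from emgfatigue.io import MvcReference


def _ols_oracle(t, y):
    """Closed-form simple OLS, written independently of the implementation."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tm, ym = t.mean(), y.mean()
    slope = np.sum((t - tm) * (y - ym)) / np.sum((t - tm) ** 2)
    return ym - slope * tm, slope


class TestSegmentRms:
    def test_constant_signal(self):
        assert segment_rms(np.full(100, 3.5)) == pytest.approx(3.5)

    def test_alternating_sign(self):
        x = np.tile([2.0, -2.0], 50)
        assert segment_rms(x) == pytest.approx(2.0)

    def test_sinusoid_closed_form(self):
        t = np.arange(2000) / 2000.0
        assert segment_rms(np.sin(2 * np.pi * 10 * t)) == pytest.approx(1 / np.sqrt(2), rel=1e-6)

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segment_rms(np.arange(10.0), (5, 5))


class TestNormalizeRms:
    REF = MvcReference(rms={"L5_left": 100.0})

    def test_identity(self):
        assert normalize_rms(100.0, self.REF, "L5_left") == pytest.approx(1.0)

    def test_above_reference(self):
        # a cyclic value 21% above the isometric reference normalizes to 1.21
        assert normalize_rms(121.0, self.REF, "L5_left") == pytest.approx(1.21)

    def test_zero(self):
        assert normalize_rms(0.0, self.REF, "L5_left") == 0.0

    def test_missing_channel(self):
        with pytest.raises(KeyError):
            normalize_rms(1.0, self.REF, "L2_left")


class TestFitTrend:
    def test_exact_line_recovers_its_coefficients(self):
        t = np.linspace(2.0, 90.0, 21)
        res = fit_line(t, 1.0 - 0.002 * t)
        assert res.initial_value == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(-0.002, abs=1e-14)
        assert res.normalized_slope == pytest.approx(-0.2, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_series_has_zero_slope(self):
        res = fit_line(np.linspace(0, 10, 8), np.full(8, 4.2))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.initial_value == pytest.approx(4.2)

    def test_matches_closed_form_ols_oracle(self, rng):
        for _ in range(50):
            t = np.sort(rng.uniform(0, 100, 21))
            y = rng.normal(size=21)
            res = fit_line(t, y)
            b0, b1 = _ols_oracle(t, y)
            assert res.initial_value == pytest.approx(b0, abs=1e-9)
            assert res.slope == pytest.approx(b1, abs=1e-12)

    def test_monte_carlo_recovery_of_normalized_slope(self, rng):
        # 21 cycles over ~84 s, noise sd 5% of the initial value
        truth = -0.11  # %/s
        t = np.linspace(9.0, 89.0, 21)
        est = []
        for _ in range(100):
            y = 1.0 * (1 + truth / 100.0 * t) + rng.normal(0, 0.05, 21)
            est.append(fit_line(t, y).normalized_slope)
        assert np.median(est) == pytest.approx(truth, abs=0.08)
        assert np.std(est) < 0.08

    def test_intercept_is_extrapolated_to_exercise_onset(self):
        # drop the early cycles: initial value must still refer to t = 0
        t = np.linspace(10.0, 90.0, 19)
        res = fit_line(t, 2.0 - 0.01 * t)
        assert res.initial_value == pytest.approx(2.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_line(np.arange(4.0), np.arange(4.0))

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_line(np.full(6, 3.0), np.arange(6.0))

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=1000.0))
    def test_scale_equivariance(self, scale):
        t = np.linspace(1.0, 80.0, 21)
        y = 1.5 - 0.003 * t + 0.01 * np.sin(t)
        base = fit_line(t, y)
        scaled = fit_line(t, scale * y)
        assert scaled.initial_value == pytest.approx(scale * base.initial_value, rel=1e-9)
        assert scaled.slope == pytest.approx(scale * base.slope, rel=1e-9)
        assert scaled.normalized_slope == pytest.approx(base.normalized_slope, rel=1e-7)

    def test_fit_trend_wraps_series(self):
        s = FatigueSeries("RMS", "L5_left", "concentric", np.linspace(0, 20, 6), np.linspace(1, 2, 6))
        assert fit_trend(s).slope == pytest.approx(0.05)


def _trend(init, nslope):
    return TrendSummary(
        initial_value=init,
        slope=init * nslope / 100.0,
        normalized_slope=nslope,
        n_points=21,
        r_squared=0.9,
    )


CHANNELS = ("L1_left", "L1_right", "L2_left", "L2_right", "L5_left", "L5_right")


class TestAggregateSubject:
    def _uniform_trends(self, init=1.0, nslope=-0.1):
        return {
            (param, ch, phase): _trend(init, nslope)
            for param in ("RMS", "IMDF")
            for ch in CHANNELS
            for phase in ("concentric", "eccentric")
        }

    def test_identical_channels_aggregate_to_the_common_value(self):
        summary = aggregate_subject(self._uniform_trends(init=1.2, nslope=-0.15))
        for row in ("all", "L5", "L2", "L1", "most_negative"):
            e = summary.entries[("RMS", "concentric", row)]
            assert e.initial_value == pytest.approx(1.2)
            assert e.normalized_slope == pytest.approx(-0.15)

    def test_all_electrodes_is_the_mean_of_levels(self):
        trends = self._uniform_trends()
        for ch in CHANNELS:
            level = ch.split("_")[0]
            init = {"L1": 1.0, "L2": 2.0, "L5": 3.0}[level]
            trends[("RMS", ch, "concentric")] = _trend(init, -0.1)
        summary = aggregate_subject(trends)
        assert summary.entries[("RMS", "concentric", "all")].initial_value == pytest.approx(2.0)

    def test_sides_averaged_within_level(self):
        trends = self._uniform_trends()
        trends[("IMDF", "L5_left", "eccentric")] = _trend(60.0, -0.1)
        trends[("IMDF", "L5_right", "eccentric")] = _trend(80.0, -0.3)
        summary = aggregate_subject(trends)
        e = summary.entries[("IMDF", "eccentric", "L5")]
        assert e.initial_value == pytest.approx(70.0)
        assert e.normalized_slope == pytest.approx(-0.2)

    def test_most_negative_electrode_selected_per_parameter(self):
        trends = self._uniform_trends()
        trends[("IMDF", "L2_right", "concentric")] = _trend(55.0, -0.9)
        trends[("RMS", "L1_left", "concentric")] = _trend(1.1, -0.5)
        summary = aggregate_subject(trends)
        assert summary.most_negative_channel[("IMDF", "concentric")] == "L2_right"
        assert summary.most_negative_channel[("RMS", "concentric")] == "L1_left"
        assert summary.entries[("IMDF", "concentric", "most_negative")].initial_value == pytest.approx(55.0)

    def test_missing_channel_rejected(self):
        trends = self._uniform_trends()
        del trends[("RMS", "L5_left", "concentric")]
        with pytest.raises(ValueError, match="missing trend"):
            aggregate_subject(trends)


class TestConcEccRatio:
    def test_reference_cohort_worked_examples(self):
        # multifidus (L5) and iliocostalis (L1) initial-value ratios
        assert round(conc_ecc_ratio(1.21, 0.68), 2) == 1.78
        assert round(conc_ecc_ratio(1.22, 0.63), 2) == 1.94

    def test_equal_inputs(self):
        assert conc_ecc_ratio(0.7, 0.7) == pytest.approx(1.0)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            conc_ecc_ratio(1.0, 0.0)
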