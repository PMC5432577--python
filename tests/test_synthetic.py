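"""Generator calibration: kinematics, amplitude, spectrum, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

from emgfatigue.fatigue import segment_rms
from emgfatigue.synthetic import (
    SyntheticConfig,
    _shaped_noise,
    emg_shape_psd,
    generate_kinematics,
    generate_semg,
    shape_scale_for_median,
)

RATE = 2000.0


def _span_rms(x, seg, rate=RATE):
    i0, i1 = int(round(seg["t_start"] * rate)), int(round(seg["t_end"] * rate))
    return segment_rms(x, (i0, i1))


class TestKinematics:
    def test_trace_duration_and_range(self):
        cfg = SyntheticConfig(n_cycles=25, cycle_duration=4.0)
        t, angle, acc, spans = generate_kinematics(cfg)
        assert t[-1] == pytest.approx(100.0 - 1 / cfg.accel_rate)
        assert angle.min() == pytest.approx(0.0, abs=1e-9)
        assert angle.max() == pytest.approx(40.0, abs=1e-6)
        # one maximum excursion per cycle
        at_top = angle > 39.999
        n_blocks = np.sum(np.diff(np.concatenate([[0], at_top.astype(int)])) == 1)
        assert n_blocks == 25

    def test_accelerometer_is_gravity_projection(self):
        cfg = SyntheticConfig(n_cycles=2)
        _, angle, acc, _ = generate_kinematics(cfg)
        assert acc[angle == 0.0][0] == 0.0
        assert acc.max() == pytest.approx(np.sin(np.deg2rad(40)), abs=1e-6)
        assert acc.max() == pytest.approx(0.643, abs=5e-4)

    def test_phase_spans_partition_and_alternate(self):
        cfg = SyntheticConfig(n_cycles=7)
        _, _, _, spans = generate_kinematics(cfg)
        assert spans[0].t_start == 0.0
        assert spans[-1].t_end == pytest.approx(cfg.duration)
        for a, b in zip(spans[:-1], spans[1:]):
            assert a.t_end == pytest.approx(b.t_start)
            assert {a.phase, b.phase} == {"eccentric", "concentric"}
        assert all(s.phase == "eccentric" for s in spans[::2])

    def test_angle_range_beyond_ninety_rejected(self):
        with pytest.raises(ValueError, match="90"):
            generate_kinematics(SyntheticConfig(angle_range=95.0))


class TestSpectralShape:
    def test_shape_median_scales_to_target(self):
        # median of the band-limited (20-500 Hz) shape equals the target
        for target in (40.0, 60.0, 90.0):
            fl, fh = shape_scale_for_median(target)
            f = np.linspace(20.0, 500.0, 192001)
            s = emg_shape_psd(f, fl, fh)
            c = np.cumsum(s)
            med = np.interp(0.5 * c[-1], c, f)
            assert med == pytest.approx(target, abs=0.05)

    def test_spectral_calibration_periodogram(self):
        # 10 s stationary segments; empirical median within 2 Hz of the
        # target when averaged over 20 seeds
        meds = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = _shaped_noise(r, 20000, RATE, 60.0)
            f, p = periodogram(x, RATE)
            c = np.cumsum(p)
            meds.append(np.interp(0.5 * c[-1], c, f))
        assert np.mean(meds) == pytest.approx(60.0, abs=2.0)


class TestGeneratedTrial:
    def test_identical_seed_bit_identical_output(self):
        cfg = SyntheticConfig(seed=11, n_cycles=2)
        a = generate_semg(cfg)
        b = generate_semg(cfg)
        for ch in cfg.channels:
            assert np.array_equal(a[0].semg[ch], b[0].semg[ch])
            assert np.array_equal(a[1].semg[ch], b[1].semg[ch])
        assert np.array_equal(a[0].accel_z, b[0].accel_z)

    def test_rms_calibration_within_3_percent(self):
        errs = []
        for seed in range(20):
            cfg = SyntheticConfig(
                seed=seed, n_cycles=3,
                rms_slope_conc=0, rms_slope_ecc=0,
                imdf_slope_conc=0, imdf_slope_ecc=0,
            )
            cyclic, _, truth = generate_semg(cfg)
            for seg in truth["segments"]["L2_left"]:
                errs.append(_span_rms(cyclic.semg["L2_left"], seg) / seg["rms_uv"] - 1)
        assert abs(np.mean(errs)) < 0.03

    def test_conc_ecc_amplitude_ratio_recovered(self):
        ratios = []
        for seed in range(20):
            cfg = SyntheticConfig(
                seed=seed, n_cycles=4,
                rms_slope_conc=0, rms_slope_ecc=0,
            )
            cyclic, _, truth = generate_semg(cfg)
            x = cyclic.semg["L5_left"]
            conc = [_span_rms(x, s) for s in truth["segments"]["L5_left"] if s["phase"] == "concentric"]
            ecc = [_span_rms(x, s) for s in truth["segments"]["L5_left"] if s["phase"] == "eccentric"]
            ratios.append(np.mean(conc) / np.mean(ecc))
        assert np.mean(ratios) == pytest.approx(1.85, abs=0.06)

    def test_imdf_drift_changes_theoretical_median_linearly(self):
        # -0.108 %/s over 100 s -> the last cycle's target is ~10.6% below
        # the first cycle's (mid-times 1 s and 99 s)
        cfg = SyntheticConfig(seed=0, n_cycles=25, imdf_slope_conc=-0.00108, imdf_slope_ecc=-0.00108)
        _, _, truth = generate_semg(
            dataclasses.replace(cfg, channels=("L5_left", "L5_right", "L2_left", "L2_right", "L1_left", "L1_right"))
        )
        segs = [s for s in truth["segments"]["L5_left"] if s["phase"] == "concentric"]
        drop = 1 - segs[-1]["imdf_hz"] / segs[0]["imdf_hz"]
        expected = 1 - (1 - 0.00108 * segs[-1]["t_mid"]) / (1 - 0.00108 * segs[0]["t_mid"])
        assert drop == pytest.approx(expected, abs=1e-12)
        assert drop == pytest.approx(0.108, abs=0.01)

    def test_drift_past_band_edge_rejected(self):
        cfg = SyntheticConfig(seed=0, n_cycles=25, imdf_slope_conc=0.2)
        with pytest.raises(ValueError, match="band|Nyquist"):
            generate_semg(cfg)

    def test_ground_truth_spans_match_config(self, small_trial):
        cfg, cyclic, _, truth = small_trial
        spans = truth["phase_spans"]
        assert len(spans) == 2 * cfg.n_cycles
        assert spans[0]["t_start"] == 0.0
        assert spans[-1]["t_end"] == pytest.approx(cfg.duration)
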