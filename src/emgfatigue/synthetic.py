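"""Synthetic cyclic back-extension trials with known ground truth.

The generator emulates the study conditions of a cyclic submaximal trunk
extension exercise: 25 movement cycles of ~4 s between upright (0°) and
forward-flexed (40°), six surface-EMG channels (multifidus at L5,
longissimus at L2, iliocostalis lumborum at L1, both sides) sampled at
2000 Hz, and a single-axis lever-arm accelerometer sampled at 160 Hz.

Each half-cycle of EMG is band-shaped Gaussian noise whose theoretical
spectrum follows the classic two-pole surface-EMG shape

    S(f) ∝ fh⁴ · f² / ((f² + fl²) · (f² + fh²)²)

with the frequency axis scaled so the spectral median matches a configured
instantaneous median frequency (IMDF), and the amplitude scaled to a
configured RMS.  Linear per-cycle drift of RMS and IMDF — the quantities
the downstream fatigue indices estimate — is imposed piecewise per
half-cycle, frozen within a half-cycle and updated at its mid-time.

Ground truth (phase boundaries, per-half-cycle target RMS/IMDF, MVC RMS)
is returned as a sidecar structure that the analysis pipeline never reads;
it exists solely so parameter-recovery tests can score the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np

from .io import Recording, parse_label

__all__ = [
    "SyntheticConfig",
    "PhaseSpan",
    "generate_kinematics",
    "generate_semg",
    "generate_trial",
    "emg_shape_psd",
    "shape_scale_for_median",
]

G_CONST = 9.81  # m/s^2, only the ratio acc/g matters here

DEFAULT_CHANNELS = (
    "L1_left",
    "L1_right",
    "L2_left",
    "L2_right",
    "L5_left",
    "L5_right",
)

#: default initial IMDF (Hz) per vertebral level; the multifidus (L5) runs
#: highest and the iliocostalis (L1) lowest in healthy back extensors
DEFAULT_IMDF0 = {"L5": 70.0, "L2": 57.0, "L1": 53.0}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic trial.

    Slopes are signed fractions of the initial value per second; e.g.
    ``imdf_slope_conc = -0.0011`` imposes a concentric IMDF decline of
    -0.11% of the initial value per second, the scale observed in fatiguing
    submaximal back-extension exercise.
    """

    n_cycles: int = 25
    cycle_duration: float = 4.0  # s; eccentric + concentric half
    angle_range: float = 40.0  # degrees of trunk flexion
    semg_rate: float = 2000.0  # Hz
    accel_rate: float = 160.0  # Hz
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    rms_conc0: float = 121.0  # µV, initial concentric RMS target
    conc_ecc_amplitude_ratio: float = 1.85
    rms_slope_conc: float = 0.0013  # fraction of initial value / s
    rms_slope_ecc: float = 0.0
    imdf0: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_IMDF0))
    imdf_slope_conc: float = -0.0011
    imdf_slope_ecc: float = -0.0011
    noise_floor: float = 0.75  # µV RMS additive white noise
    mvc_rms: float = 100.0  # µV, RMS of the 80% MVC reference contraction
    mvc_duration: float = 8.0  # s
    seed: int = 0

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be > 0")
        if not (0.0 <= self.angle_range < 90.0):
            raise ValueError(
                "angle_range must lie in [0, 90) degrees: the arcsine "
                "inversion of the accelerometer is ambiguous beyond 90"
            )
        if self.conc_ecc_amplitude_ratio <= 0:
            raise ValueError("conc_ecc_amplitude_ratio must be > 0")
        nyq = self.semg_rate / 2.0
        for level, f0 in self.imdf0.items():
            if not (0.0 < f0 < nyq):
                raise ValueError(f"imdf0[{level!r}] = {f0} Hz outside (0, Nyquist)")
        for label in self.channels:
            level, _ = parse_label(label)
            if level not in self.imdf0:
                raise ValueError(f"no imdf0 entry for level {level!r}")
        if self.mvc_duration < 6.0:
            raise ValueError("mvc_duration must be >= 6 s")

    @property
    def duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d


@dataclass(frozen=True)
class PhaseSpan:
    """Ground-truth half-cycle: phase label plus its time span in seconds."""

    cycle_index: int
    phase: str  # "eccentric" (0 -> 40 deg) or "concentric" (40 -> 0 deg)
    t_start: float
    t_end: float

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


#: fraction of each half-cycle spent accelerating (and decelerating)
BLEND_FRACTION = 0.2


def _paced_step(u: np.ndarray, beta: float = BLEND_FRACTION) -> np.ndarray:
    """Normalized position profile of a metronome-paced movement on [0, 1].

    Velocity ramps up over the first ``beta`` of the half-cycle with a
    half-cosine blend, holds constant over the middle, and ramps down
    symmetrically — the kinematics of a paced exercise where the moving
    portion is near constant velocity and acceleration is confined to the
    turnarounds.  Position and velocity are continuous; acceleration is
    continuous and exactly zero on the plateau.
    """
    u = np.asarray(u, dtype=float)
    # ∫ blend velocity: (τ - β·sin(πτ/β)/π) / 2 ; plateau velocity 1
    lo = u < beta
    hi = u > 1.0 - beta
    pos = np.empty_like(u)
    pos[lo] = 0.5 * (u[lo] - beta * np.sin(np.pi * u[lo] / beta) / np.pi)
    mid = ~lo & ~hi
    pos[mid] = u[mid] - beta / 2.0
    ur = 1.0 - u[hi]
    pos[hi] = (1.0 - beta) - (0.5 * (ur - beta * np.sin(np.pi * ur / beta) / np.pi))
    return pos / (1.0 - beta)


def _phase_spans(cfg: SyntheticConfig) -> list[PhaseSpan]:
    half = cfg.cycle_duration / 2.0
    spans = []
    for c in range(cfg.n_cycles):
        t0 = c * cfg.cycle_duration
        spans.append(PhaseSpan(c, "eccentric", t0, t0 + half))
        spans.append(PhaseSpan(c, "concentric", t0 + half, t0 + cfg.cycle_duration))
    return spans


def generate_kinematics(
    cfg: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[PhaseSpan]]:
    """Synthesize the trunk-angle trace and the accelerometer z-axis.

    Each cycle is an eccentric half (0° -> ``angle_range``, trunk flexing
    forward) followed by a concentric half (back to 0°), each following a
    paced constant-velocity profile with smooth turnaround blends over
    ``cycle_duration / 2``.  The accelerometer reading is the gravity
    projection ``acc_z = g·sin(α)`` expressed in units of g, i.e.
    ``sin(α)``.

    Returns ``(t, angle_deg, acc_z_g, spans)`` on the accelerometer clock.
    """
    cfg.validate()
    n = int(round(cfg.duration * cfg.accel_rate))
    t = np.arange(n) / cfg.accel_rate
    half = cfg.cycle_duration / 2.0
    k = np.floor(t / half).astype(int)  # half-cycle index
    u = t / half - k
    s = _paced_step(u)
    rising = k % 2 == 0  # eccentric: angle increases
    angle = np.where(rising, s, 1.0 - s) * cfg.angle_range
    acc_z = np.sin(np.deg2rad(angle))
    return t, angle, acc_z, _phase_spans(cfg)


# ---------------------------------------------------------------------------
# spectral shape


def emg_shape_psd(f: np.ndarray, fl: float, fh: float) -> np.ndarray:
    """Two-pole surface-EMG power spectral shape (unnormalized)."""
    f2 = np.asarray(f, dtype=float) ** 2
    return fh**4 * f2 / ((f2 + fl**2) * (f2 + fh**2) ** 2)


# dimensionless pole ratio of the shape: fh = _POLE_RATIO * fl
_POLE_RATIO = 2.5

#: recording bandwidth (Hz) of the emulated SEMG chain; the synthesized
#: spectrum is zero outside this band, like hardware-filtered EMG
BAND = (20.0, 500.0)


def _band_median(scale: float, band: tuple[float, float] = BAND) -> float:
    """Spectral median of the band-limited shape with poles (scale, 2.5*scale)."""
    f = np.linspace(band[0], band[1], 9601)
    s = emg_shape_psd(f, scale, _POLE_RATIO * scale)
    c = np.cumsum(s)
    return float(np.interp(0.5 * c[-1], c, f))


@lru_cache(maxsize=4096)
def shape_scale_for_median(
    target_median_hz: float, band: tuple[float, float] = BAND
) -> tuple[float, float]:
    """Pole frequencies ``(fl, fh)`` giving the band-limited shape a chosen
    spectral median.

    The median is computed on the recording band, so it is what a
    periodogram of the synthesized (band-limited) signal measures.  Solved
    by bisection; the band-limited median is monotone in the pole scale.
    """
    lo, hi = band
    if not (lo < target_median_hz < hi):
        raise ValueError(f"target median {target_median_hz} Hz outside the band {band}")
    s_lo, s_hi = 1e-3, 10.0 * hi
    for _ in range(60):
        mid = 0.5 * (s_lo + s_hi)
        if _band_median(mid, band) < target_median_hz:
            s_lo = mid
        else:
            s_hi = mid
    scale = 0.5 * (s_lo + s_hi)
    return scale, _POLE_RATIO * scale


def _shaped_noise(
    rng: np.random.Generator, n: int, rate: float, median_hz: float
) -> np.ndarray:
    """Gaussian noise spectrally shaped to the band-limited EMG PSD.

    The spectrum follows the two-pole shape inside the recording band and
    is zero outside it; the spectral median equals ``median_hz``.  The
    realization is normalized to unit RMS; the caller scales it.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    fl, fh = shape_scale_for_median(median_hz)
    gain = np.sqrt(emg_shape_psd(f, fl, fh))
    gain[(f < BAND[0]) | (f > BAND[1])] = 0.0
    spec *= gain
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


@lru_cache(maxsize=4096)
def _prefilter_attenuation(median_hz: float, rate: float) -> float:
    """RMS shrinkage of the shaped noise under the 20/500 Hz zero-phase
    pre-filter of the analysis chain.

    Forward-backward filtering multiplies the PSD by |H|⁴; the shaped
    spectrum loses a little power near the band edges.  Targets are
    divided by this factor so post-filter RMS matches the configured
    value.
    """
    from scipy import signal as _signal

    from .io import _bandpass_sos

    f = np.linspace(BAND[0], BAND[1], 4801)
    fl, fh = shape_scale_for_median(median_hz)
    s = emg_shape_psd(f, fl, fh)
    _, h = _signal.sosfreqz(_bandpass_sos(rate), worN=f, fs=rate)
    power_gain = np.abs(h) ** 4
    return float(np.sqrt(np.sum(s * power_gain) / np.sum(s)))


# ---------------------------------------------------------------------------
# trial synthesis


def generate_semg(cfg: SyntheticConfig) -> tuple[Recording, Recording, dict]:
    """Synthesize the cyclic trial, the MVC reference trial, and ground truth.

    Per channel and half-cycle, band-shaped noise is scaled so the segment's
    empirical RMS equals the drifted target exactly and its spectral median
    equals the drifted IMDF target in expectation; white noise at the
    configured noise floor is then added.  The 80% MVC reference recording
    is stationary shaped noise at the channel's initial IMDF with RMS
    ``mvc_rms``.

    Returns ``(cyclic, mvc80, ground_truth)``.  ``ground_truth`` holds the
    phase spans, per-channel per-half-cycle targets, MVC RMS, and the
    config; the analysis pipeline must never consume it.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t_acc, angle, acc_z, spans = generate_kinematics(cfg)
    n = int(round(cfg.duration * cfg.semg_rate))
    nyq = cfg.semg_rate / 2.0
    rms_ecc0 = cfg.rms_conc0 / cfg.conc_ecc_amplitude_ratio

    truth_segments: dict[str, list[dict]] = {}
    semg: dict[str, np.ndarray] = {}
    for label in cfg.channels:
        level, _ = parse_label(label)
        f0 = cfg.imdf0[level]
        x = np.empty(n)
        seg_truth = []
        for span in spans:
            i0 = int(round(span.t_start * cfg.semg_rate))
            i1 = int(round(span.t_end * cfg.semg_rate))
            i1 = min(i1, n)
            if span.phase == "concentric":
                rms0, rms_sl, imdf_sl = cfg.rms_conc0, cfg.rms_slope_conc, cfg.imdf_slope_conc
            else:
                rms0, rms_sl, imdf_sl = rms_ecc0, cfg.rms_slope_ecc, cfg.imdf_slope_ecc
            target_rms = rms0 * (1.0 + rms_sl * span.t_mid)
            target_imdf = f0 * (1.0 + imdf_sl * span.t_mid)
            if target_rms <= 0:
                raise ValueError("RMS drift drove the target below zero")
            if not (BAND[0] < target_imdf < min(nyq, BAND[1])):
                raise ValueError(
                    f"IMDF drift drove the target to {target_imdf:.1f} Hz, "
                    f"outside the recording band {BAND} / Nyquist {nyq:.0f} Hz"
                )
            amp = target_rms / _prefilter_attenuation(target_imdf, cfg.semg_rate)
            x[i0:i1] = amp * _shaped_noise(rng, i1 - i0, cfg.semg_rate, target_imdf)
            seg_truth.append(
                {
                    "cycle_index": span.cycle_index,
                    "phase": span.phase,
                    "t_start": span.t_start,
                    "t_end": span.t_end,
                    "t_mid": span.t_mid,
                    "rms_uv": target_rms,
                    "imdf_hz": target_imdf,
                }
            )
        x += cfg.noise_floor * rng.standard_normal(n)
        semg[label] = x
        truth_segments[label] = seg_truth

    meta = {"subject_id": f"synthetic-{cfg.seed}", "age": None, "sex": None}
    cyclic = Recording(
        semg=semg,
        semg_rate=cfg.semg_rate,
        accel_z=acc_z,
        accel_rate=cfg.accel_rate,
        meta=meta | {"trial": "cyclic"},
    )

    n_mvc = int(round(cfg.mvc_duration * cfg.semg_rate))
    n_acc_mvc = int(round(cfg.mvc_duration * cfg.accel_rate))
    mvc_semg = {}
    for label in cfg.channels:
        level, _ = parse_label(label)
        amp = cfg.mvc_rms / _prefilter_attenuation(cfg.imdf0[level], cfg.semg_rate)
        y = amp * _shaped_noise(rng, n_mvc, cfg.semg_rate, cfg.imdf0[level])
        y += cfg.noise_floor * rng.standard_normal(n_mvc)
        mvc_semg[label] = y
    mvc = Recording(
        semg=mvc_semg,
        semg_rate=cfg.semg_rate,
        accel_z=np.zeros(n_acc_mvc),
        accel_rate=cfg.accel_rate,
        meta=meta | {"trial": "mvc80"},
    )

    truth = {
        "config": cfg.to_dict(),
        "phase_spans": [
            {
                "cycle_index": s.cycle_index,
                "phase": s.phase,
                "t_start": s.t_start,
                "t_end": s.t_end,
            }
            for s in spans
        ],
        "segments": truth_segments,
        "mvc_rms_uv": {label: cfg.mvc_rms for label in cfg.channels},
        "normalized": {
            "rms_conc0": cfg.rms_conc0 / cfg.mvc_rms,
            "rms_ecc0": rms_ecc0 / cfg.mvc_rms,
        },
    }
    return cyclic, mvc, truth


def generate_trial(cfg: SyntheticConfig) -> tuple[Recording, Recording, dict]:
    """Alias of :func:`generate_semg`; named for the CLI's vocabulary."""
    return generate_semg(cfg)
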