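"""Trunk kinematics from the lever-arm accelerometer and cycle segmentation.

The trunk flexion angle is approximated from the accelerometer z-axis as
``α = asin(acc / g)``; angular velocity is obtained by zero-phase 8th-order
1 Hz low-pass filtering of the angle followed by a first derivative.
Cycles are delimited by alternating angle minima (upright, ≈0°) and maxima
(flexed, ≈40°): the rising half (flexing, resisting the load) is the
eccentric phase, the falling half (extending back upright) the concentric
phase.  Within each half-cycle only a centered window (default 1 s) is
retained, and half-cycles whose retained window contains disproportionally
large angular acceleration are flagged, as are the first and last cycles
of the exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "KinematicsTrace",
    "CycleSegment",
    "SegmentationError",
    "trunk_angle",
    "angular_velocity",
    "kinematics_trace",
    "segment_cycles",
    "retained_cycles",
]

#: tolerance on |acc/g| above 1 before declaring sensor miscalibration
ACC_CLAMP_TOL = 0.05


class SegmentationError(RuntimeError):
    """Raised when a trial cannot be segmented into enough valid cycles."""


@dataclass
class KinematicsTrace:
    """Angle/velocity time series on the accelerometer clock."""

    t: np.ndarray  # s
    angle: np.ndarray  # degrees, raw arcsine estimate
    angle_filtered: np.ndarray  # degrees, 1 Hz zero-phase low-pass
    velocity: np.ndarray  # degrees/s
    rate: float  # Hz
    acc: np.ndarray  # g, the raw z-axis input


@dataclass
class CycleSegment:
    """One labeled half-cycle span, expressed on the SEMG sample clock."""

    cycle_index: int
    phase: str  # "concentric" | "eccentric"
    start: int  # SEMG sample, inclusive
    stop: int  # SEMG sample, exclusive
    duration: float  # s
    excluded: bool = False
    reason: str | None = None


def trunk_angle(acc_g: np.ndarray, g: float = 1.0) -> np.ndarray:
    """Trunk angle in degrees from the accelerometer z-axis.

    ``acc_g`` is the measured acceleration in the same units as ``g``
    (pass g = 1 when the trace is already expressed in units of g).
    Ratios slightly outside [-1, 1] (up to ``ACC_CLAMP_TOL``) are clamped
    with a warning; larger excursions indicate a miscalibrated sensor.
    """
    ratio = np.asarray(acc_g, dtype=float) / g
    if not np.all(np.isfinite(ratio)):
        raise ValueError("accelerometer trace contains non-finite samples")
    over = np.abs(ratio) > 1.0
    if np.any(np.abs(ratio) > 1.0 + ACC_CLAMP_TOL):
        raise ValueError(
            f"|acc/g| exceeds {1 + ACC_CLAMP_TOL:.2f}: sensor miscalibration?"
        )
    if np.any(over):
        warnings.warn(
            f"clamped {int(over.sum())} accelerometer samples with |acc/g| > 1",
            stacklevel=2,
        )
        ratio = np.clip(ratio, -1.0, 1.0)
    return np.degrees(np.arcsin(ratio))


def _lowpass_angle(angle: np.ndarray, rate: float, cutoff: float = 1.0, order: int = 8) -> np.ndarray:
    sos = signal.butter(order, cutoff / (rate / 2.0), btype="lowpass", output="sos")
    return signal.sosfiltfilt(sos, angle)


def angular_velocity(angle_deg: np.ndarray, rate: float) -> np.ndarray:
    """Angular velocity (deg/s): 1 Hz 8th-order zero-phase low-pass + derivative."""
    if rate <= 2.0:
        raise ValueError("sampling rate must exceed 2 Hz for a 1 Hz low-pass")
    if len(angle_deg) < 3.0 * rate:
        raise ValueError("angle trace shorter than the 3 s filter warm-up")
    smooth = _lowpass_angle(np.asarray(angle_deg, dtype=float), rate)
    return np.gradient(smooth, 1.0 / rate)


def kinematics_trace(acc_g: np.ndarray, rate: float, g: float = 1.0) -> KinematicsTrace:
    """Full kinematics estimate from a raw accelerometer z-axis trace."""
    acc_g = np.asarray(acc_g, dtype=float)
    angle = trunk_angle(acc_g, g=g)
    smooth = _lowpass_angle(angle, rate)
    vel = angular_velocity(angle, rate)
    t = np.arange(len(acc_g)) / rate
    return KinematicsTrace(t=t, angle=angle, angle_filtered=smooth, velocity=vel, rate=rate, acc=acc_g)


def _alternating_extrema(angle_f: np.ndarray, rate: float, min_sep_s: float) -> list[tuple[int, str]]:
    """Indices of alternating minima/maxima of the filtered angle.

    Runs of same-type extrema are collapsed to the most extreme one.
    """
    dist = max(1, int(round(min_sep_s * rate)))
    prominence = 0.1 * max(np.ptp(angle_f), 1e-9)
    maxima, _ = signal.find_peaks(angle_f, distance=dist, prominence=prominence)
    minima, _ = signal.find_peaks(-angle_f, distance=dist, prominence=prominence)
    ext = sorted([(i, "max") for i in maxima] + [(i, "min") for i in minima])
    cleaned: list[tuple[int, str]] = []
    for idx, kind in ext:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx, _ = cleaned[-1]
            better = angle_f[idx] > angle_f[prev_idx] if kind == "max" else angle_f[idx] < angle_f[prev_idx]
            if better:
                cleaned[-1] = (idx, kind)
        else:
            cleaned.append((idx, kind))
    return cleaned


def segment_cycles(
    kin: KinematicsTrace,
    semg_rate: float,
    *,
    window_s: float = 1.0,
    accel_percentile: float = 90.0,
    omit_edge: int = 2,
    min_cycles: int = 15,
    cycle_duration_hint: float = 4.0,
) -> list[CycleSegment]:
    """Segment a cyclic trial into labeled concentric/eccentric spans.

    Parameters
    ----------
    window_s
        Length of the retained window, centered within each half-cycle.
    accel_percentile
        Half-cycles whose retained window contains angular acceleration
        above this trial-level percentile of ``|angular acceleration|``
        are flagged excluded — a scale-free rule for rejecting portions
        with disproportionally large trunk acceleration.
    omit_edge
        Number of cycles flagged excluded at each end of the exercise.
    min_cycles
        Minimum number of fully retained cycles; fewer raises
        :class:`SegmentationError`.

    Returns all segments, including excluded ones (flagged with a reason),
    with spans re-expressed as half-open intervals on the SEMG clock.
    """
    angle_f = kin.angle_filtered
    n = len(angle_f)
    ext = _alternating_extrema(angle_f, kin.rate, min_sep_s=0.4 * cycle_duration_hint)
    if len(ext) < 3:
        raise SegmentationError(
            f"fewer than min_cycles={min_cycles} cycles retained: "
            f"only {len(ext)} angle extrema detected"
        )
    # Pad virtual extrema at the trace ends so edge half-cycles are bookkept;
    # they are flagged excluded below.
    virtual: set[int] = set()
    first_idx, first_kind = ext[0]
    if first_idx > 0:
        virtual.add(0)
        ext.insert(0, (0, "min" if first_kind == "max" else "max"))
    last_idx, last_kind = ext[-1]
    if last_idx < n - 1:
        virtual.add(n - 1)
        ext.append((n - 1, "min" if last_kind == "max" else "max"))

    accel = np.gradient(kin.velocity, 1.0 / kin.rate)
    thresh = np.percentile(np.abs(accel), accel_percentile)

    # cycles start at minima (upright); count minima seen so far
    segments: list[CycleSegment] = []
    cycle = -1
    for (i0, k0), (i1, _k1) in zip(ext[:-1], ext[1:]):
        if k0 == "min":
            cycle += 1
        if cycle < 0:
            # trace started mid-cycle on a falling half; treat as cycle 0
            cycle = 0
        phase = "eccentric" if k0 == "min" else "concentric"
        mid = 0.5 * (i0 + i1)
        half_w = 0.5 * window_s * kin.rate
        w0 = int(round(max(i0, mid - half_w)))
        w1 = int(round(min(i1, mid + half_w)))
        if w1 <= w0:
            continue
        excluded, reason = False, None
        if i0 in virtual or i1 in virtual:
            excluded, reason = True, "edge"
        elif np.any(np.abs(accel[w0:w1]) > thresh):
            excluded, reason = True, "acceleration"
        start = int(round(w0 / kin.rate * semg_rate))
        stop = int(round(w1 / kin.rate * semg_rate))
        segments.append(
            CycleSegment(
                cycle_index=cycle,
                phase=phase,
                start=start,
                stop=stop,
                duration=(w1 - w0) / kin.rate,
                excluded=excluded,
                reason=reason,
            )
        )

    n_cycles = max((s.cycle_index for s in segments), default=-1) + 1
    for s in segments:
        if s.cycle_index < omit_edge or s.cycle_index >= n_cycles - omit_edge:
            if not s.excluded:
                s.excluded, s.reason = True, "edge"

    if len(retained_cycles(segments)) < min_cycles:
        raise SegmentationError(
            f"fewer than min_cycles={min_cycles} cycles retained "
            f"({len(retained_cycles(segments))} of {n_cycles})"
        )
    return segments


def retained_cycles(segments: list[CycleSegment]) -> list[int]:
    """Cycle indices for which both phases were retained (not excluded)."""
    by_cycle: dict[int, set[str]] = {}
    for s in segments:
        if not s.excluded:
            by_cycle.setdefault(s.cycle_index, set()).add(s.phase)
    return sorted(c for c, phases in by_cycle.items() if phases == {"concentric", "eccentric"})
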