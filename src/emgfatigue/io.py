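"""Recording container I/O, pre-filtering, and MVC reference amplitude.

A *trial* is stored as a directory of plain-text artifacts:

``semg.csv``
    Column ``t_s`` plus one column per channel label (``L5_left`` ...),
    amplitudes in microvolts.
``accel.csv``
    Columns ``t_s`` and ``acc_z_g`` — the accelerometer z-axis in units of g.
``meta.json``
    Subject/trial metadata: ``subject_id``, ``age``, ``sex``, ``trial``
    (``cyclic`` or ``mvc80``), ``semg_rate_hz``, ``accel_rate_hz``.

Amplitude normalization uses a sustained isometric reference contraction at
80% of maximum voluntary contraction (MVC): the per-channel RMS over the
window from 2 s to 5 s of that recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Recording",
    "MvcReference",
    "SchemaError",
    "LEVELS",
    "SIDES",
    "parse_label",
    "read_recording",
    "write_recording",
    "bandpass_semg",
    "mvc_reference",
]

LEVELS = ("L1", "L2", "L5")
SIDES = ("left", "right")

#: default band edges (Hz) of the surface-EMG pre-filter
HIGHPASS_HZ = 20.0
LOWPASS_HZ = 500.0


class SchemaError(ValueError):
    """A recording container failed validation; the message names the field."""


def parse_label(label: str) -> tuple[str, str]:
    """Split ``'L5_left'`` into ``('L5', 'left')``, validating both parts."""
    parts = label.split("_")
    if len(parts) != 2 or parts[0] not in LEVELS or parts[1] not in SIDES:
        raise SchemaError(
            f"channel label {label!r}: expected '<level>_<side>' with "
            f"level in {LEVELS} and side in {SIDES}"
        )
    return parts[0], parts[1]


@dataclass
class Recording:
    """One trial: synchronized SEMG channels plus the lever-arm accelerometer.

    Attributes
    ----------
    semg : dict[str, np.ndarray]
        Channel label -> samples in microvolts. All channels share one
        length and one sampling rate.
    semg_rate : float
        SEMG sampling rate in Hz.
    accel_z : np.ndarray
        Accelerometer z-axis samples in units of g.
    accel_rate : float
        Accelerometer sampling rate in Hz.
    meta : dict
        ``subject_id``, ``age``, ``sex``, ``trial`` in {"cyclic", "mvc80"}.
    """

    semg: dict[str, np.ndarray]
    semg_rate: float
    accel_z: np.ndarray
    accel_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.semg_rate <= 0:
            raise SchemaError("semg_rate: must be > 0")
        if self.accel_rate <= 0:
            raise SchemaError("accel_rate: must be > 0")
        if not self.semg:
            raise SchemaError("semg: at least one channel required")
        lengths = set()
        for label, x in self.semg.items():
            parse_label(label)
            lengths.add(len(x))
        if len(lengths) != 1:
            raise SchemaError("semg: channels have unequal lengths")
        if len(set(self.semg)) != len(self.semg):
            raise SchemaError("semg: duplicate channel labels")
        self.accel_z = np.asarray(self.accel_z, dtype=float)
        if self.accel_z.ndim != 1:
            raise SchemaError("accel_z: must be one-dimensional")
        trial = self.meta.get("trial")
        if trial is not None and trial not in ("cyclic", "mvc80"):
            raise SchemaError(f"meta.trial: {trial!r} not in ('cyclic', 'mvc80')")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.semg.values())))

    @property
    def duration(self) -> float:
        """Trial duration in seconds (SEMG clock)."""
        return self.n_samples / self.semg_rate

    @property
    def channels(self) -> list[str]:
        return list(self.semg)


@dataclass(frozen=True)
class MvcReference:
    """Per-channel RMS (µV) of the 80% MVC reference contraction."""

    rms: dict[str, float]
    window_s: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        for label, value in self.rms.items():
            if not value > 0:
                raise ValueError(f"MVC RMS for {label!r} must be > 0, got {value}")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` to ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = rec.n_samples
    semg = pd.DataFrame({"t_s": np.arange(n) / rec.semg_rate} | {k: v for k, v in rec.semg.items()})
    semg.to_csv(path / "semg.csv", index=False, float_format="%.6f")
    accel = pd.DataFrame(
        {"t_s": np.arange(len(rec.accel_z)) / rec.accel_rate, "acc_z_g": rec.accel_z}
    )
    accel.to_csv(path / "accel.csv", index=False, float_format="%.8f")
    meta = dict(rec.meta)
    meta["semg_rate_hz"] = rec.semg_rate
    meta["accel_rate_hz"] = rec.accel_rate
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a trial directory written by :func:`write_recording`.

    Raises :class:`SchemaError` naming the missing/malformed field.
    """
    path = Path(path)
    for name in ("semg.csv", "accel.csv", "meta.json"):
        if not (path / name).exists():
            raise SchemaError(f"{name}: missing from {path}")
    try:
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"meta.json: malformed JSON ({exc})") from exc
    for key in ("semg_rate_hz", "accel_rate_hz"):
        if key not in meta:
            raise SchemaError(f"meta.json: missing {key}")
    semg_rate = float(meta.pop("semg_rate_hz"))
    accel_rate = float(meta.pop("accel_rate_hz"))
    semg_df = pd.read_csv(path / "semg.csv")
    if "t_s" not in semg_df.columns:
        raise SchemaError("semg.csv: missing t_s column")
    channels = {c: semg_df[c].to_numpy(float) for c in semg_df.columns if c != "t_s"}
    accel_df = pd.read_csv(path / "accel.csv")
    if "acc_z_g" not in accel_df.columns:
        raise SchemaError("accel.csv: missing acc_z_g column")
    return Recording(
        semg=channels,
        semg_rate=semg_rate,
        accel_z=accel_df["acc_z_g"].to_numpy(float),
        accel_rate=accel_rate,
        meta=meta,
    )


def _bandpass_sos(rate: float, order: int = 4) -> np.ndarray:
    nyq = rate / 2.0
    hp = signal.butter(order, HIGHPASS_HZ / nyq, btype="highpass", output="sos")
    lp = signal.butter(order, LOWPASS_HZ / nyq, btype="lowpass", output="sos")
    return np.vstack([hp, lp])


def bandpass_semg(x: np.ndarray, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase 20 Hz high-pass + 500 Hz low-pass Butterworth cascade.

    Both filters are of the given order and applied forward-backward
    (``sosfiltfilt``), so the output has no phase distortion and the same
    length as the input.
    """
    if rate <= 2 * LOWPASS_HZ:
        raise ValueError(
            f"sampling rate {rate} Hz too low: the {LOWPASS_HZ:.0f} Hz low-pass "
            "cutoff must lie below Nyquist"
        )
    x = np.asarray(x, dtype=float)
    return signal.sosfiltfilt(_bandpass_sos(rate, order), x)


def mvc_reference(rec: Recording, window_s: tuple[float, float] = (2.0, 5.0)) -> MvcReference:
    """Per-channel RMS over ``[window_s[0], window_s[1])`` of an MVC recording.

    The signal is band-passed first. The recording must cover the window.
    """
    t0, t1 = window_s
    if rec.duration < t1:
        raise ValueError(
            f"MVC recording lasts {rec.duration:.2f} s; need at least {t1:.0f} s"
        )
    i0 = int(round(t0 * rec.semg_rate))
    i1 = int(round(t1 * rec.semg_rate))
    rms = {}
    for label, x in rec.semg.items():
        y = bandpass_semg(x, rec.semg_rate)[i0:i1]
        rms[label] = float(np.sqrt(np.mean(y**2)))
    return MvcReference(rms=rms, window_s=(t0, t1))
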