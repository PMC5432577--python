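"""Per-cycle fatigue series, trend fitting, and subject-level aggregation.

For each retained half-cycle segment and channel, two scalars are
computed: the RMS amplitude (normalized by the 80% MVC reference) and the
segment IMDF (Hz).  An ordinary least-squares line through the per-cycle
values versus segment mid-time yields the two fatigue indices per channel
and phase:

* the *initial value* — the intercept at exercise onset (t = 0), i.e. the
  extrapolated value at the start of the exercise even when early cycles
  were excluded;
* the *normalized slope* — the slope expressed as percent of the initial
  value per second.

A rising RMS trend and a falling IMDF trend both index progressing
localized muscle fatigue.  Subject-level aggregation mirrors the standard
reporting structure for six back-extensor electrodes: left/right trend
parameters are averaged within vertebral level (L1, L2, L5), the
"all electrodes" entry is the mean of the three levels, and the "most
negative electrode" entry is the single channel with the smallest
normalized slope for that parameter and phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import MvcReference, Recording, bandpass_semg, parse_label
from .kinematics import CycleSegment
from .tfd import segment_imdf

__all__ = [
    "FatigueSeries",
    "TrendSummary",
    "TrendAggregate",
    "SubjectSummary",
    "segment_rms",
    "normalize_rms",
    "fit_line",
    "fit_trend",
    "compute_series",
    "aggregate_subject",
    "conc_ecc_ratio",
    "analyze_trial",
]

PARAMETERS = ("RMS", "IMDF")
PHASES = ("concentric", "eccentric")
ROWS = ("all", "L5", "L2", "L1", "most_negative")

MIN_TREND_POINTS = 5


@dataclass
class FatigueSeries:
    """Per-cycle scalar values for one parameter x channel x phase.

    ``values`` are MVC-normalized (unitless) for RMS and absolute Hz for
    IMDF; ``t_mid`` are segment mid-times in seconds from exercise onset.
    """

    parameter: str  # "RMS" | "IMDF"
    channel: str  # e.g. "L5_left"
    phase: str  # "concentric" | "eccentric"
    t_mid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t_mid = np.asarray(self.t_mid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.parameter not in PARAMETERS:
            raise ValueError(f"parameter must be one of {PARAMETERS}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if np.any(np.diff(self.t_mid) <= 0):
            raise ValueError("t_mid must be strictly increasing")


@dataclass(frozen=True)
class TrendSummary:
    """Least-squares line through a fatigue series.

    ``normalized_slope`` is 100 * slope / initial_value (% of the initial
    value per second); NaN when the intercept is zero.
    """

    initial_value: float  # intercept at t = 0, units of the series
    slope: float  # units / s
    normalized_slope: float  # % initial value / s
    n_points: int
    r_squared: float


@dataclass(frozen=True)
class TrendAggregate:
    """Trend parameters after averaging channels (e.g. left+right)."""

    initial_value: float
    slope: float
    normalized_slope: float


@dataclass
class SubjectSummary:
    """Per-subject table rows for both parameters and phases.

    ``entries[(parameter, phase, row)]`` with row in
    ``("all", "L5", "L2", "L1", "most_negative")``; the selected channel
    behind each most-negative entry is in ``most_negative_channel``;
    ``ratios[(parameter, row)]`` holds concentric / eccentric ratios of
    initial values, and ``slope_ratios`` the same for normalized slopes.
    """

    subject: str
    entries: dict = field(default_factory=dict)
    most_negative_channel: dict = field(default_factory=dict)
    ratios: dict = field(default_factory=dict)
    slope_ratios: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "entries": {
                "|".join(k): vars(v) if isinstance(v, TrendAggregate) else v
                for k, v in self.entries.items()
            },
            "most_negative_channel": {"|".join(k): v for k, v in self.most_negative_channel.items()},
            "ratios": {"|".join(k): v for k, v in self.ratios.items()},
            "slope_ratios": {"|".join(k): v for k, v in self.slope_ratios.items()},
        }


def segment_rms(x: np.ndarray, span: tuple[int, int] | None = None) -> float:
    """Root-mean-square of ``x`` over the half-open sample span."""
    if span is not None:
        x = np.asarray(x)[span[0] : span[1]]
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty span")
    return float(np.sqrt(np.mean(x**2)))


def normalize_rms(rms: float, mvc: MvcReference, channel: str) -> float:
    """RMS expressed as a fraction of the channel's 80% MVC reference RMS."""
    if channel not in mvc.rms:
        raise KeyError(f"channel {channel!r} missing from MVC reference")
    return rms / mvc.rms[channel]


def fit_line(t: np.ndarray, y: np.ndarray) -> TrendSummary:
    """Ordinary least squares of ``y`` on ``t`` with trend bookkeeping."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    t, y = t[ok], y[ok]
    n = len(t)
    if n < MIN_TREND_POINTS:
        raise ValueError(f"need >= {MIN_TREND_POINTS} points for a trend, got {n}")
    if np.ptp(t) == 0:
        raise ValueError("degenerate series: all abscissae equal")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    norm = 100.0 * slope / intercept if intercept != 0 else math.nan
    return TrendSummary(
        initial_value=float(intercept),
        slope=float(slope),
        normalized_slope=float(norm),
        n_points=n,
        r_squared=r2,
    )


def fit_trend(series: FatigueSeries) -> TrendSummary:
    """Least-squares trend of a fatigue series (value vs mid-time)."""
    return fit_line(series.t_mid, series.values)


def conc_ecc_ratio(conc: float, ecc: float) -> float:
    """Concentric / eccentric ratio of a summary value."""
    if ecc == 0:
        raise ZeroDivisionError("eccentric value is zero")
    return conc / ecc


def compute_series(
    recording: Recording,
    mvc: MvcReference,
    segments: list[CycleSegment],
    *,
    sigma: float = 1.0,
    n_instants: int = 128,
    prefiltered: dict[str, np.ndarray] | None = None,
) -> list[FatigueSeries]:
    """Per-cycle RMS and IMDF series for every channel x phase.

    The SEMG is band-passed once per channel; each retained segment then
    contributes one MVC-normalized RMS value and one segment IMDF.
    """
    filtered = prefiltered or {
        ch: bandpass_semg(x, recording.semg_rate) for ch, x in recording.semg.items()
    }
    out: list[FatigueSeries] = []
    rate = recording.semg_rate
    for channel, x in filtered.items():
        for phase in PHASES:
            spans = sorted(
                (s for s in segments if not s.excluded and s.phase == phase),
                key=lambda s: s.start,
            )
            t_mid, rms_vals, imdf_vals = [], [], []
            for s in spans:
                seg = x[s.start : s.stop]
                t_mid.append(0.5 * (s.start + s.stop) / rate)
                rms_vals.append(normalize_rms(segment_rms(seg), mvc, channel))
                imdf_vals.append(
                    segment_imdf(
                        seg,
                        rate,
                        sigma,
                        n_instants=n_instants,
                        provenance={"channel": channel, "cycle": s.cycle_index, "phase": phase},
                    ).summary
                )
            out.append(FatigueSeries("RMS", channel, phase, np.array(t_mid), np.array(rms_vals)))
            out.append(FatigueSeries("IMDF", channel, phase, np.array(t_mid), np.array(imdf_vals)))
    return out


def aggregate_subject(
    trends: dict[tuple[str, str, str], TrendSummary],
    subject: str = "",
) -> SubjectSummary:
    """Aggregate per-channel trends into the standard subject table rows.

    Parameters
    ----------
    trends
        ``(parameter, channel, phase) -> TrendSummary`` for all six
        channels, both parameters and phases.

    Raises ``ValueError`` if any of the six channels is missing for some
    parameter x phase.
    """
    channels = sorted({ch for (_, ch, _) in trends})
    if len(channels) != 6:
        raise ValueError(f"expected 6 channels, got {len(channels)}: {channels}")
    levels = ("L1", "L2", "L5")
    summary = SubjectSummary(subject=subject)
    for parameter in PARAMETERS:
        for phase in PHASES:
            per_level: dict[str, TrendAggregate] = {}
            for level in levels:
                pair = [ch for ch in channels if parse_label(ch)[0] == level]
                if len(pair) != 2:
                    raise ValueError(f"level {level} does not have two sides: {pair}")
                ts = []
                for ch in pair:
                    key = (parameter, ch, phase)
                    if key not in trends:
                        raise ValueError(f"missing trend for {key}")
                    ts.append(trends[key])
                per_level[level] = TrendAggregate(
                    initial_value=float(np.mean([t.initial_value for t in ts])),
                    slope=float(np.mean([t.slope for t in ts])),
                    normalized_slope=float(np.mean([t.normalized_slope for t in ts])),
                )
                summary.entries[(parameter, phase, level)] = per_level[level]
            summary.entries[(parameter, phase, "all")] = TrendAggregate(
                initial_value=float(np.mean([per_level[lv].initial_value for lv in levels])),
                slope=float(np.mean([per_level[lv].slope for lv in levels])),
                normalized_slope=float(np.mean([per_level[lv].normalized_slope for lv in levels])),
            )
            # most negative electrode: smallest normalized slope of the six
            best_ch = min(
                channels, key=lambda ch: trends[(parameter, ch, phase)].normalized_slope
            )
            t = trends[(parameter, best_ch, phase)]
            summary.entries[(parameter, phase, "most_negative")] = TrendAggregate(
                initial_value=t.initial_value,
                slope=t.slope,
                normalized_slope=t.normalized_slope,
            )
            summary.most_negative_channel[(parameter, phase)] = best_ch
    for parameter in PARAMETERS:
        for row in ROWS:
            conc = summary.entries[(parameter, "concentric", row)]
            ecc = summary.entries[(parameter, "eccentric", row)]
            if ecc.initial_value != 0:
                summary.ratios[(parameter, row)] = conc.initial_value / ecc.initial_value
            if ecc.normalized_slope not in (0.0,) and np.isfinite(ecc.normalized_slope):
                summary.slope_ratios[(parameter, row)] = (
                    conc.normalized_slope / ecc.normalized_slope
                )
    return summary


def analyze_trial(
    cyclic: Recording,
    mvc: MvcReference,
    segments: list[CycleSegment],
    *,
    sigma: float = 1.0,
    n_instants: int = 128,
    subject: str | None = None,
) -> tuple[list[FatigueSeries], dict, SubjectSummary]:
    """End-to-end single-trial analysis.

    Returns the per-cycle series, the per-channel trend dictionary keyed
    by ``(parameter, channel, phase)``, and the aggregated subject
    summary.
    """
    series = compute_series(cyclic, mvc, segments, sigma=sigma, n_instants=n_instants)
    trends = {(s.parameter, s.channel, s.phase): fit_trend(s) for s in series}
    subject_id = subject if subject is not None else str(cyclic.meta.get("subject_id", ""))
    summary = aggregate_subject(trends, subject=subject_id)
    return series, trends, summary
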