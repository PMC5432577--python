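"""Orchestration: simulate -> validate -> segment -> tfd -> analyze -> report.

Every stage reads and writes plain CSV/JSON artifacts in a per-trial
directory so any stage can be inspected, replaced, or re-run in
isolation:

``trial/cyclic/``, ``trial/mvc80/``
    the two recording containers (see :mod:`emgfatigue.io`);
``trial/ground_truth.json``
    generator sidecar, written by ``simulate`` only and never read back;
``trial/segments.csv``
    one row per half-cycle (cycle_index, phase, start/stop sample on the
    SEMG clock, duration, excluded flag + reason);
``trial/imdf.csv``
    one row per channel x retained segment: mid-time, segment IMDF (Hz)
    and MVC-normalized RMS;
``trial/summary.json``
    the per-subject trend aggregates, most-negative-electrode selections
    and concentric/eccentric ratios.

A cohort run adds ``tables/`` with the concentric-vs-eccentric and
age x gender report tables, plus ``manifest.json`` recording the config,
seed, and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import fatigue, stats
from .io import MvcReference, read_recording, write_recording
from .kinematics import CycleSegment, kinematics_trace, retained_cycles, segment_cycles
from .io import mvc_reference
from .synthetic import SyntheticConfig, generate_semg

__all__ = [
    "PipelineOptions",
    "simulate_trial",
    "validate_trial",
    "segment_trial",
    "analyze_trial_dir",
    "run_cohort",
]


@dataclasses.dataclass
class PipelineOptions:
    """Tunable knobs of the analysis stages (defaults mirror the modules)."""

    window_s: float = 1.0
    accel_percentile: float = 90.0
    omit_edge: int = 2
    min_cycles: int = 15
    cycle_duration_hint: float = 4.0
    sigma: float = 1.0
    n_instants: int = 128
    n_boot: int = 2000

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineOptions":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline options: {sorted(unknown)}")
        return cls(**d)


def simulate_trial(cfg: SyntheticConfig, out_dir: str | Path) -> Path:
    """Generate one synthetic subject and write its trial directory."""
    out_dir = Path(out_dir)
    cyclic, mvc, truth = generate_semg(cfg)
    write_recording(cyclic, out_dir / "cyclic")
    write_recording(mvc, out_dir / "mvc80")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return out_dir


def validate_trial(trial_dir: str | Path) -> dict:
    """Read both recordings back, raising a schema error on any defect."""
    trial_dir = Path(trial_dir)
    cyclic = read_recording(trial_dir / "cyclic")
    mvc = read_recording(trial_dir / "mvc80")
    return {
        "trial": str(trial_dir),
        "channels": cyclic.channels,
        "cyclic_duration_s": cyclic.duration,
        "mvc_duration_s": mvc.duration,
    }


def segment_trial(trial_dir: str | Path, opts: PipelineOptions | None = None) -> pd.DataFrame:
    """Segment a trial's cyclic recording; writes and returns segments.csv."""
    opts = opts or PipelineOptions()
    trial_dir = Path(trial_dir)
    cyclic = read_recording(trial_dir / "cyclic")
    kin = kinematics_trace(cyclic.accel_z, cyclic.accel_rate)
    segments = segment_cycles(
        kin,
        cyclic.semg_rate,
        window_s=opts.window_s,
        accel_percentile=opts.accel_percentile,
        omit_edge=opts.omit_edge,
        min_cycles=opts.min_cycles,
        cycle_duration_hint=opts.cycle_duration_hint,
    )
    df = pd.DataFrame(
        [
            {
                "cycle_index": s.cycle_index,
                "phase": s.phase,
                "start_sample": s.start,
                "end_sample": s.stop,
                "duration_s": s.duration,
                "excluded": s.excluded,
                "reason": s.reason or "",
            }
            for s in segments
        ]
    )
    df.to_csv(trial_dir / "segments.csv", index=False)
    return df


def _segments_from_csv(df: pd.DataFrame) -> list[CycleSegment]:
    return [
        CycleSegment(
            cycle_index=int(r.cycle_index),
            phase=str(r.phase),
            start=int(r.start_sample),
            stop=int(r.end_sample),
            duration=float(r.duration_s),
            excluded=bool(r.excluded),
            reason=str(r.reason) or None,
        )
        for r in df.itertuples()
    ]


def analyze_trial_dir(trial_dir: str | Path, opts: PipelineOptions | None = None) -> dict:
    """Run tfd + fatigue analysis for one trial; writes imdf.csv, summary.json."""
    opts = opts or PipelineOptions()
    trial_dir = Path(trial_dir)
    cyclic = read_recording(trial_dir / "cyclic")
    mvc_rec = read_recording(trial_dir / "mvc80")
    mvc = mvc_reference(mvc_rec)
    seg_path = trial_dir / "segments.csv"
    if not seg_path.exists():
        segment_trial(trial_dir, opts)
    segments = _segments_from_csv(pd.read_csv(seg_path))

    series, trends, summary = fatigue.analyze_trial(
        cyclic, mvc, segments, sigma=opts.sigma, n_instants=opts.n_instants
    )

    rows = []
    by_key = {(s.parameter, s.channel, s.phase): s for s in series}
    for (param, channel, phase), s in by_key.items():
        if param != "IMDF":
            continue
        rms_series = by_key[("RMS", channel, phase)]
        for t_mid, imdf_hz, rms_norm in zip(s.t_mid, s.values, rms_series.values):
            rows.append(
                {
                    "channel": channel,
                    "phase": phase,
                    "t_mid_s": t_mid,
                    "imdf_hz": imdf_hz,
                    "rms_normalized": rms_norm,
                }
            )
    pd.DataFrame(rows).to_csv(trial_dir / "imdf.csv", index=False)

    out = summary.to_dict()
    out["trends"] = {
        "|".join(k): dataclasses.asdict(v) for k, v in trends.items()
    }
    with open(trial_dir / "summary.json", "w") as fh:
        json.dump(out, fh, indent=1)
    return out


def run_cohort(
    cohort_dir: str | Path,
    *,
    n_subjects: int = 10,
    seed: int = 0,
    config: SyntheticConfig | None = None,
    opts: PipelineOptions | None = None,
    simulate: bool = True,
) -> dict:
    """Simulate (optionally) and analyze a cohort end-to-end.

    Returns the manifest; writes per-trial artifacts plus cohort
    ``tables/rms_conc_vs_ecc.csv``, ``tables/imdf_conc_vs_ecc.csv``.
    """
    opts = opts or PipelineOptions()
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    trial_dirs = []
    if simulate:
        base = config or SyntheticConfig()
        for i in range(n_subjects):
            cfg = dataclasses.replace(base, seed=seed + i)
            trial_dirs.append(simulate_trial(cfg, cohort_dir / f"subject_{i:03d}"))
    else:
        trial_dirs = sorted(p.parent.parent for p in cohort_dir.glob("*/cyclic/meta.json"))

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "options": dataclasses.asdict(opts),
        "synthetic_config": (config or SyntheticConfig()).to_dict() if simulate else None,
        "n_subjects": len(trial_dirs),
        "trials": [],
    }
    summaries = []
    for td in trial_dirs:
        try:
            validate_trial(td)
            seg_df = segment_trial(td, opts)
            summary = analyze_trial_dir(td, opts)
        except Exception as exc:  # noqa: BLE001 - abort names the stage+trial
            raise RuntimeError(f"pipeline failed for trial {td.name}: {exc}") from exc
        segs = _segments_from_csv(seg_df)
        manifest["trials"].append(
            {"trial": td.name, "retained_cycles": len(retained_cycles(segs))}
        )
        summaries.append(summary)

    tables_dir = cohort_dir / "tables"
    tables_dir.mkdir(exist_ok=True)
    rows = ("all", "L5", "L2", "L1", "most_negative")
    for param, fname in (("RMS", "rms_conc_vs_ecc.csv"), ("IMDF", "imdf_conc_vs_ecc.csv")):
        conc = {
            r: np.array([s["entries"][f"{param}|concentric|{r}"]["initial_value"] for s in summaries])
            for r in rows
        }
        ecc = {
            r: np.array([s["entries"][f"{param}|eccentric|{r}"]["initial_value"] for s in summaries])
            for r in rows
        }
        if len(summaries) >= 5:
            table = stats.cohort_table(conc, ecc, n_boot=opts.n_boot, seed=seed)
            table.to_csv(tables_dir / fname, index=False)
    with open(cohort_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
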