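# emgfatigue

Localized muscle-fatigue analysis of surface EMG (SEMG) recorded from the
back extensors during cyclic, submaximal trunk-extension exercise.

The exercise alternates an **eccentric** half-cycle (the trunk flexes
forward from upright 0° to 40° while the muscles resist the load) and a
**concentric** half-cycle (the trunk extends back to upright).  Six
bipolar electrodes record the multifidus (L5), longissimus (L2) and
iliocostalis lumborum (L1) bilaterally at 2 kHz; a single-axis
accelerometer on the dynamometer lever arm (160 Hz) provides the
kinematics.  The package answers the question: *how do amplitude and
spectral fatigue indices evolve over ~25 exercise cycles, separately for
the concentric and eccentric phases?*

## Method

For each trial the pipeline computes, per channel and phase:

1. **Kinematics & segmentation.** Trunk angle `α = asin(acc/g)`; angular
   velocity from an 8th-order 1 Hz zero-phase low-pass plus first
   derivative.  Cycles are delimited by alternating angle extrema; within
   each half-cycle a centered 1 s window is retained, half-cycles with
   disproportionally large angular acceleration inside the window are
   flagged, and the first/last 2 cycles are omitted.
2. **Amplitude.** RMS of the 20–500 Hz band-passed SEMG over each
   retained window, normalized by the channel RMS of a sustained 80% MVC
   (maximum voluntary contraction) reference, measured over its 2–5 s
   window.
3. **Spectrum.** A Choi-Williams (Cohen-class) time-frequency
   distribution of each window and the instantaneous median frequency
   (IMDF) — the frequency splitting each instantaneous spectrum's power
   in half; the window's summary IMDF is the median over time instants.
4. **Fatigue indices.** Ordinary least squares of the per-cycle values
   against segment mid-time: the *initial value* (intercept at exercise
   onset, `b₀`) and the *normalized slope* (`100·b₁/b₀`, % of the initial
   value per second).  Rising RMS and falling IMDF both index progressing
   localized fatigue.
5. **Aggregation & statistics.** Left/right averaged per level, the
   "all electrodes" mean of the three levels, and the most-negative
   electrode per parameter; cohort contrasts (concentric vs eccentric,
   age × gender on conc/ecc ratios) via percentile-bootstrap median
   tests.

A seedable synthetic-trial generator with known ground truth (imposed
amplitude ratio and linear RMS/IMDF drifts in band-limited, EMG-shaped
noise) makes every stage testable by parameter recovery; no external data
is needed.

## Worked example

```python
from emgfatigue import (SyntheticConfig, generate_semg, mvc_reference,
                        kinematics_trace, segment_cycles, analyze_trial)

cfg = SyntheticConfig(seed=1)          # 25 cycles, 6 channels, 2 kHz
cyclic, mvc_rec, truth = generate_semg(cfg)
kin = kinematics_trace(cyclic.accel_z, cyclic.accel_rate)
segments = segment_cycles(kin, cyclic.semg_rate)
series, trends, summary = analyze_trial(cyclic, mvc_reference(mvc_rec), segments)

e = summary.entries[("RMS", "concentric", "all")]
print(f"RMS conc: initial {e.initial_value:.3f}, slope {e.normalized_slope:+.3f} %/s")
e = summary.entries[("IMDF", "concentric", "all")]
print(f"IMDF conc: initial {e.initial_value:.1f} Hz, slope {e.normalized_slope:+.3f} %/s")
print(f"conc/ecc RMS ratio: {summary.ratios[('RMS', 'all')]:.2f}")
```

prints (seed 1; the generator imposed +0.13 %/s RMS drift, −0.11 %/s IMDF
drift and a 1.85 amplitude ratio):

```
RMS conc: initial 1.210, slope +0.135 %/s
IMDF conc: initial 63.8 Hz, slope -0.102 %/s
conc/ecc RMS ratio: 1.86
```

The normalized RMS initial value ≈ 1.2 means the concentric cycles start
~20% *above* the 80% MVC reference amplitude; the negative IMDF slope is
the spectral compression that marks accumulating fatigue.

The same pipeline is scriptable from the shell:

```bash
emgfatigue simulate --out trial/ --seed 1
emgfatigue validate trial/
emgfatigue segment trial/
emgfatigue analyze trial/
emgfatigue run cohort/ --subjects 10 --seed 7     # end-to-end + report tables
```

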