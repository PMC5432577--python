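"""Reference cohort medians for cyclic back-extension fatigue indices.

Median values from a reference cohort of 87 healthy adults performing 25
cyclic trunk extensions at 50% MVC (0°–40°, ~4 s/cycle), used as worked-
example inputs and to pick realistic synthetic-generator defaults.  RMS
initial values are normalized to the 80% MVC reference contraction
(unitless); IMDF initial values are in Hz; slopes are in % of the initial
value per second.

Each table maps a report row to ``(concentric, eccentric)`` medians.
Rows: ``all`` (mean of the three levels), the vertebral levels ``L5``
(multifidus), ``L2`` (longissimus), ``L1`` (iliocostalis lumborum), and
``most_negative`` (the electrode with the most negative normalized
slope).
"""

RMS_INITIAL_MEDIANS = {
    "all": (1.21, 0.67),
    "L5": (1.21, 0.68),
    "L2": (1.24, 0.66),
    "L1": (1.22, 0.63),
    "most_negative": (1.08, 0.54),
}

RMS_SLOPE_MEDIANS = {  # % initial value / s
    "all": (0.132, 0.038),
    "L5": (0.071, 0.055),
    "L2": (0.118, -0.002),
    "L1": (0.126, -0.002),
    "most_negative": (-0.027, -0.169),
}

IMDF_INITIAL_MEDIANS = {  # Hz
    "all": (57.79, 59.63),
    "L5": (69.65, 73.93),
    "L2": (56.54, 60.16),
    "L1": (52.66, 53.37),
    "most_negative": (48.93, 49.31),
}

IMDF_SLOPE_MEDIANS = {  # % initial value / s
    "all": (-0.108, -0.110),
    "L5": (-0.147, -0.162),
    "L2": (-0.099, -0.129),
    "L1": (-0.074, -0.066),
    "most_negative": (-0.232, -0.263),
}
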