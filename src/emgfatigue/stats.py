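"""Median-based group comparisons via percentile bootstrap.

Fatigue indices across subjects are markedly skewed, so group contrasts
are made on medians rather than means.  Both tests are percentile
bootstraps of median contrasts:

* one-way — concentric vs eccentric within subjects (paired by default:
  resample subjects and bootstrap the median of within-subject
  differences) or two independent groups;
* two-way — a 2x2 design (e.g. age group x gender) on a per-subject
  ratio; main effects and the interaction are contrasts of cell medians,
  bootstrapped by resampling within cells.

The two-sided p-value is twice the smaller tail probability of the
bootstrap distribution of the contrast around zero (equal-tailed
percentile test), with half-weight on exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupComparison",
    "median_test_oneway",
    "median_test_twoway",
    "cohort_table",
]

DEFAULT_N_BOOT = 2000


@dataclass
class GroupComparison:
    """Result of one bootstrap median comparison."""

    statistic: float  # the median contrast on the observed data
    p_value: float
    medians: dict = field(default_factory=dict)  # group -> median
    quartiles: dict = field(default_factory=dict)  # group -> (Q25, Q75)
    n: dict = field(default_factory=dict)  # group -> sample size
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _two_sided_p(boot: np.ndarray) -> float:
    """Equal-tailed percentile-bootstrap p for H0: contrast = 0."""
    b = len(boot)
    below = float(np.sum(boot < 0)) + 0.5 * float(np.sum(boot == 0))
    p_low = below / b
    return float(min(1.0, 2.0 * min(p_low, 1.0 - p_low)))


def _summaries(name: str, x: np.ndarray, out: GroupComparison) -> None:
    out.medians[name] = float(np.median(x))
    q25, q75 = np.percentile(x, [25, 75])
    out.quartiles[name] = (float(q25), float(q75))
    out.n[name] = int(len(x))


def median_test_oneway(
    group_a: np.ndarray,
    group_b: np.ndarray,
    *,
    paired: bool = True,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> GroupComparison:
    """Bootstrap test of a difference of medians between two groups.

    Paired (the default, appropriate when every subject contributes both
    conditions): the statistic is the median of within-subject differences
    and subjects are resampled.  Unpaired: the statistic is the difference
    of group medians and each group is resampled independently.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each group needs at least 5 observations")
    rng = np.random.default_rng(seed)
    result = GroupComparison(statistic=0.0, p_value=1.0)
    _summaries("a", a, result)
    _summaries("b", b, result)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        d = a - b
        result.statistic = float(np.median(d))
        idx = rng.integers(0, len(d), size=(n_boot, len(d)))
        boot = np.median(d[idx], axis=1)
        result.method = f"paired percentile bootstrap of the median difference, B={n_boot}, seed={seed}"
    else:
        result.statistic = float(np.median(a) - np.median(b))
        ia = rng.integers(0, len(a), size=(n_boot, len(a)))
        ib = rng.integers(0, len(b), size=(n_boot, len(b)))
        boot = np.median(a[ia], axis=1) - np.median(b[ib], axis=1)
        result.method = f"two-sample percentile bootstrap of the median difference, B={n_boot}, seed={seed}"
    if np.all(boot == boot[0]):
        # degenerate data (zero variance): decide on the observed contrast
        result.p_value = 1.0 if boot[0] == 0 else 0.0
    else:
        result.p_value = _two_sided_p(boot)
    return result


def median_test_twoway(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    *,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> dict[str, GroupComparison]:
    """Bootstrap 2x2 median tests: two main effects and the interaction.

    ``factor_a`` and ``factor_b`` are per-observation labels with exactly
    two levels each (e.g. younger/older, female/male).  With cell medians
    m_ij, the main effect of A is ``mean_j(m_1j) - mean_j(m_2j)``, of B
    symmetric, and the interaction is the difference of differences
    ``(m_11 - m_12) - (m_21 - m_22)``.  Cells are resampled independently.
    """
    v = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    la, lb = np.unique(fa), np.unique(fb)
    if len(la) != 2 or len(lb) != 2:
        raise ValueError("both factors must have exactly two levels")
    cells = {}
    for i, ai in enumerate(la):
        for j, bj in enumerate(lb):
            cell = v[(fa == ai) & (fb == bj)]
            if len(cell) < 5:
                raise ValueError(f"cell ({ai}, {bj}) has fewer than 5 observations")
            cells[(i, j)] = cell

    rng = np.random.default_rng(seed)
    boot_m = {}
    for key, cell in cells.items():
        idx = rng.integers(0, len(cell), size=(n_boot, len(cell)))
        boot_m[key] = np.median(cell[idx], axis=1)
    obs_m = {key: np.median(cell) for key, cell in cells.items()}

    def contrasts(m):
        eff_a = 0.5 * (m[(0, 0)] + m[(0, 1)]) - 0.5 * (m[(1, 0)] + m[(1, 1)])
        eff_b = 0.5 * (m[(0, 0)] + m[(1, 0)]) - 0.5 * (m[(0, 1)] + m[(1, 1)])
        inter = (m[(0, 0)] - m[(0, 1)]) - (m[(1, 0)] - m[(1, 1)])
        return {"a": eff_a, "b": eff_b, "interaction": inter}

    obs = contrasts(obs_m)
    boot = contrasts(boot_m)
    out = {}
    for name in ("a", "b", "interaction"):
        bt = np.asarray(boot[name])
        if np.all(bt == bt[0]):
            p = 1.0 if bt[0] == 0 else 0.0
        else:
            p = _two_sided_p(bt)
        gc = GroupComparison(
            statistic=float(obs[name]),
            p_value=p,
            method=f"2x2 percentile bootstrap of cell-median contrasts, B={n_boot}, seed={seed}",
        )
        for (i, j), cell in cells.items():
            _summaries(f"{la[i]}|{lb[j]}", cell, gc)
        out[name] = gc
    return out


def cohort_table(
    conc: dict[str, np.ndarray],
    ecc: dict[str, np.ndarray],
    *,
    rows: tuple[str, ...] = ("all", "L5", "L2", "L1", "most_negative"),
    paired: bool = True,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Concentric-vs-eccentric cohort table for one parameter.

    ``conc[row]`` / ``ecc[row]`` are per-subject values for each table row
    (all electrodes, levels, most-negative electrode).  Output columns
    mirror the standard report: group medians and quartiles, the test
    statistic (median difference) and its p-value.
    """
    if len(next(iter(conc.values()))) < 2:
        raise ValueError("cohort table needs at least 2 subjects")
    records = []
    for i, row in enumerate(rows):
        res = median_test_oneway(
            np.asarray(conc[row]), np.asarray(ecc[row]),
            paired=paired, n_boot=n_boot, seed=seed + i,
        )
        records.append(
            {
                "row": row,
                "conc_median": res.medians["a"],
                "conc_q25": res.quartiles["a"][0],
                "conc_q75": res.quartiles["a"][1],
                "ecc_median": res.medians["b"],
                "ecc_q25": res.quartiles["b"][0],
                "ecc_q75": res.quartiles["b"][1],
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame.from_records(records)
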