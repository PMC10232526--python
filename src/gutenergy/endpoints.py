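"""Small host-phenotype computations.

Incremental area under the curve (iAUC) for postprandial hormone/appetite
series sampled at -30, -15, +30, +60, +120, +180 min around each meal;
simple imputation rules for sparsely missing timepoints; motion-free sleep
from minute-level radar counts; and the energy-balance arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SampledCurve",
    "MEAL_GRID_MIN",
    "iauc",
    "impute_interior",
    "impute_locf",
    "motion_free_sleep",
    "energy_balance",
]

#: nominal sampling grid relative to each meal, minutes
MEAL_GRID_MIN = (-30, -15, 30, 60, 120, 180)


@dataclass(frozen=True)
class SampledCurve:
    """One meal's concentration (or VAS) series on the nominal grid."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        t = np.asarray(self.times, float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


def iauc(times, values, net: bool = True) -> float:
    """Trapezoidal incremental AUC in concentration*min.

    Baseline is the mean of the pre-meal samples (times < 0); the increment
    is anchored at 0 at t = 0 (no meal-time sample exists on the grid) and
    integrated over the post-meal samples.  With ``net=True`` (default)
    negative increments are retained (net iAUC); ``net=False`` clips
    increments at zero (positive iAUC).
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    pre = t < 0
    if not pre.any() or np.any(~np.isfinite(v[pre])):
        raise ValueError("baseline (pre-meal) samples are missing")
    baseline = v[pre].mean()
    post_t = np.concatenate([[0.0], t[~pre]])
    incr = np.concatenate([[0.0], v[~pre] - baseline])
    if not net:
        incr = np.clip(incr, 0.0, None)
    return float(np.trapezoid(incr, post_t))


def impute_interior(values, missing_index: int):
    """Fill one interior missing point with the mean of its neighbors."""
    v = np.asarray(values, float).copy()
    if not 0 < missing_index < v.size - 1:
        raise ValueError("interior interpolation needs both neighbors; use impute_locf at edges")
    left, right = v[missing_index - 1], v[missing_index + 1]
    if not (np.isfinite(left) and np.isfinite(right)):
        raise ValueError("both neighbors must be observed")
    v[missing_index] = (left + right) / 2.0
    return v


def impute_locf(values):
    """Last observation carried forward for a missing terminal point."""
    v = np.asarray(values, float).copy()
    if v.size == 0:
        raise ValueError("empty series")
    if np.isnan(v[0]):
        raise ValueError("no predecessor to carry forward")
    for i in range(1, v.size):
        if np.isnan(v[i]):
            v[i] = v[i - 1]
    return v


def motion_free_sleep(counts, threshold: int = 6) -> float:
    """Hours of motion-free sleep: minutes with counts strictly below threshold.

    The boundary is exclusive: a minute with exactly ``threshold`` counts of
    movement is removed.
    """
    c = np.asarray(counts)
    if c.size and (np.any(c < 0) or np.any(c != np.floor(c))):
        raise ValueError("counts must be non-negative integers")
    return float(np.count_nonzero(c < threshold)) / 60.0


def energy_balance(ei_kcal: float, ee_kcal: float, convention: str = "intake_minus_expenditure") -> float:
    """Daily energy balance in kcal (positive = surplus under the default).

    The default convention is EI - EE; ``convention=
    'expenditure_minus_intake'`` flips the sign.
    """
    if ei_kcal <= 0 or ee_kcal <= 0:
        raise ValueError("ei_kcal and ee_kcal must be > 0")
    if convention == "intake_minus_expenditure":
        return ei_kcal - ee_kcal
    if convention == "expenditure_minus_intake":
        return ee_kcal - ei_kcal
    raise ValueError(f"unknown convention {convention!r}")
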