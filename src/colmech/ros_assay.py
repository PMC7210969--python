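"""Tensile arithmetic and FOX-assay hydrogen peroxide quantification.

Stress is force over cross-sectional area (N/mm² = MPa); suspended-mass
loads convert with standard gravity 9.8 m/s² (so 350 g -> 3.43 N at the
printed precision).  Peroxide concentrations come from a linear 595 nm
absorbance calibration; the pulled-minus-untreated concentration
difference is estimated per time point with standard errors propagated
from well-level variance.  Group comparisons use the equal-variance
two-tailed two-sample t-test with the conventional star labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import STANDARD_GRAVITY
from .errors import ValidationError
from .synthetic_data import FoxCalibration

__all__ = [
    "FoxCalibration",
    "stress_from_force",
    "force_from_mass",
    "DeltaEstimate",
    "estimate_delta_concentration",
    "TTestResult",
    "two_tailed_ttest",
]


def stress_from_force(force_N: float, area_mm2: float) -> float:
    """Engineering stress in MPa from force (N) and cross-section (mm²)."""
    if area_mm2 <= 0:
        raise ValidationError("cross-sectional area must be positive")
    return force_N / area_mm2


def force_from_mass(mass_g: float) -> float:
    """Weight force (N) of a suspended mass (g) under standard gravity."""
    if mass_g < 0:
        raise ValidationError("mass must be non-negative")
    return mass_g * 1e-3 * STANDARD_GRAVITY


@dataclass
class DeltaEstimate:
    """Pulled-minus-untreated peroxide concentration at one time point."""

    time_min: float
    delta_uM: float
    se_uM: float
    pulled_uM: float
    untreated_uM: float
    n_pulled: int
    n_untreated: int


def _condition_concentration(
    absorbances: np.ndarray, calibration: FoxCalibration
) -> tuple[float, float]:
    conc = (absorbances.mean() - calibration.intercept) / calibration.slope
    if len(absorbances) > 1:
        se = absorbances.std(ddof=1) / np.sqrt(len(absorbances)) / abs(
            calibration.slope
        )
    else:
        se = 0.0
    return float(conc), float(se)


def estimate_delta_concentration(
    plate: pd.DataFrame,
    calibration: FoxCalibration,
    time_min: float | None = None,
) -> DeltaEstimate | list[DeltaEstimate]:
    """Estimate the pulled-vs-untreated H2O2 concentration difference.

    ``plate`` needs columns ``condition`` (pulled/untreated), ``time_min``
    and ``absorbance``.  With ``time_min=None`` a list with one estimate
    per time point is returned.  Concentrations are
    ``(mean A - intercept) / slope``; the standard error of the difference
    adds the two conditions' errors in quadrature.  Adding a common
    absorbance offset to both conditions leaves the difference unchanged.
    """
    if calibration.slope == 0:
        raise ValidationError("calibration slope must be nonzero")
    if time_min is None:
        return [
            estimate_delta_concentration(plate, calibration, t)
            for t in sorted(plate.time_min.unique())
        ]
    at_t = plate[np.isclose(plate.time_min.values, time_min)]
    pulled = at_t[at_t.condition == "pulled"].absorbance.values
    untreated = at_t[at_t.condition == "untreated"].absorbance.values
    if len(pulled) == 0 or len(untreated) == 0:
        raise ValidationError(
            f"both conditions must be populated at time {time_min} min"
        )
    cp, sp = _condition_concentration(pulled, calibration)
    cu, su = _condition_concentration(untreated, calibration)
    return DeltaEstimate(
        time_min=float(time_min),
        delta_uM=cp - cu,
        se_uM=float(np.hypot(sp, su)),
        pulled_uM=cp,
        untreated_uM=cu,
        n_pulled=len(pulled),
        n_untreated=len(untreated),
    )


@dataclass
class TTestResult:
    t: float
    p: float
    stars: str


def star_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def two_tailed_ttest(a, b) -> TTestResult:
    """Two-tailed, equal-variance (pooled) two-sample t-test.

    Degenerate zero-pooled-variance inputs: equal means give p = 1, unequal
    means give the p -> 0 sentinel (t = ±inf).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs at least two values")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return TTestResult(t=0.0, p=1.0, stars="")
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TTestResult(t=t, p=0.0, stars=star_label(0.0))
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       stars=star_label(float(res.pvalue)))
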