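"""From raw plate data to initial velocities.

The luminescent readout is calibrated against a UDP standard curve (ordinary
least squares of RLU on concentration), each well's trace is converted to
product concentration, the linear range is located (a conversion cap on the
limiting substrate plus a local-linearity r² gate), and the initial velocity
is the least-squares slope over that window, with its regression standard
error.  Velocities are reported in nM product/min and are *not* normalized by
enzyme: the turnover number emerges downstream from the global fit, which
carries the enzyme concentration explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ProgressCurve, StandardCurveData, VelocityObservation

__all__ = [
    "StandardCurveFit",
    "LinearRangeOptions",
    "CalibrationError",
    "LinearRangeError",
    "fit_standard_curve",
    "rlu_to_udp",
    "detect_linear_range",
    "initial_velocity",
]


class CalibrationError(ValueError):
    """The standard curve cannot serve as a calibration (e.g. nonpositive slope)."""


class LinearRangeError(ValueError):
    """No window of the progress curve satisfies the linear-range criteria."""


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS calibration line: signal = intercept + slope · [UDP]."""

    slope: float  # RLU per μM
    intercept: float  # RLU
    r_squared: float
    n: int
    slope_se: float = 0.0
    intercept_se: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"standard-curve slope must be positive, got {self.slope!r}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class LinearRangeOptions:
    """Linear-range rule: conversion cap AND local-linearity gate.

    ``max_conversion`` bounds product relative to the limiting substrate
    (bounds depletion bias); ``min_r_squared`` guards against lag or burst
    artifacts; windows shorter than ``min_points`` are rejected.
    """

    max_conversion: float = 0.10
    min_points: int = 4
    min_r_squared: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.max_conversion <= 1.0):
            raise ValueError("max_conversion must be in (0, 1]")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


def fit_standard_curve(data: StandardCurveData) -> StandardCurveFit:
    """Fit the UDP calibration line by ordinary least squares."""
    concs = np.asarray(data.udp_concs, dtype=float)
    if np.unique(concs).size < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    res = stats.linregress(concs, data.signals)
    r2 = float(res.rvalue**2)
    if res.slope <= 0:
        raise CalibrationError(
            f"standard-curve slope is {res.slope:.4g} RLU/uM; calibration failed"
        )
    return StandardCurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        n=concs.size,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


def rlu_to_udp(signal, fit: StandardCurveFit):
    """Invert the calibration: concentration (μM) = (signal − intercept)/slope.

    Background-level noise can yield slightly negative concentrations; they are
    returned as-is (clamping would bias downstream regressions).
    """
    return (np.asarray(signal, dtype=float) - fit.intercept) / fit.slope


def _window_r_squared(t: np.ndarray, y: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-30 * max(1.0, float(np.sum(y**2))):
        return 1.0  # flat trace: perfectly "linear" with slope 0
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def detect_linear_range(
    curve: ProgressCurve,
    fit: StandardCurveFit,
    options: LinearRangeOptions = LinearRangeOptions(),
) -> tuple[int, int]:
    """Longest prefix window satisfying the linear-range rule.

    Returns (start, end) indices, end inclusive.  The window always starts at
    the first sample; ``end`` is the largest index such that every converted
    concentration up to it stays at or below ``max_conversion · min(a0, b0)``
    and the local line through the window has r² ≥ ``min_r_squared``.
    """
    conc = rlu_to_udp(curve.signal, fit)
    cap = options.max_conversion * min(curve.a0, curve.b0)
    within = conc <= cap + 1e-12 * cap
    # largest prefix inside the conversion cap
    n_cap = int(np.argmin(within)) if not within.all() else conc.size
    best_end = -1
    for end in range(options.min_points - 1, n_cap):
        r2 = _window_r_squared(curve.times[: end + 1], conc[: end + 1])
        if r2 >= options.min_r_squared:
            best_end = end
    if best_end < 0:
        raise LinearRangeError(
            "no linear range: "
            f"{n_cap} of {conc.size} points within the {options.max_conversion:.0%} "
            f"conversion cap (limiting substrate {min(curve.a0, curve.b0):g} uM), "
            f"min_points={options.min_points}, min_r_squared={options.min_r_squared}"
        )
    return (0, best_end)


def initial_velocity(
    curve: ProgressCurve,
    fit: StandardCurveFit,
    options: LinearRangeOptions = LinearRangeOptions(),
) -> VelocityObservation:
    """Initial velocity (nM/min) from the slope over the detected linear range."""
    start, end = detect_linear_range(curve, fit, options)
    t = curve.times[start : end + 1]
    conc = rlu_to_udp(curve.signal[start : end + 1], fit)
    res = stats.linregress(t, conc)
    velocity_nM_min = float(res.slope) * 1e3  # μM/min -> nM/min
    se = float(res.stderr) * 1e3 if np.isfinite(res.stderr) else 0.0
    flags: tuple[str, ...] = ()
    if velocity_nM_min < 0:
        warnings.warn(
            f"negative fitted velocity ({velocity_nM_min:.3g} nM/min) in well "
            f"{curve.well_id!r}; retained unclamped",
            stacklevel=2,
        )
        flags = ("negative_velocity",)
    return VelocityObservation(
        a_conc=curve.a0,
        b_conc=curve.b0,
        velocity=velocity_nM_min,
        velocity_se=se,
        linear_window=(start, end),
        well_id=curve.well_id,
        flags=flags,
    )
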