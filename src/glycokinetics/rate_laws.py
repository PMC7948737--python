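"""Closed-form bisubstrate rate laws and their double-reciprocal geometry.

The enzyme studied here (B3GNT2, a GlcNAc transferase) turns over two
substrates: a sugar-nucleotide donor A (UDP-GlcNAc) and a disaccharide
acceptor B (LacNAc).  Three classical mechanisms are represented, each as a
closed-form initial-velocity law v([A], [B]):

* rapid-equilibrium random-order sequential —

      v = k_cat [E] [A][B] / (alpha K_A K_B + alpha K_A [B]
                              + alpha K_B [A] + [A][B])

  where K_A and K_B are dissociation constants of the binary enzyme–substrate
  complexes and alpha expresses how the binding of one substrate changes the
  affinity for the other (alpha < 1: mutual tightening);

* rapid-equilibrium compulsory-order with A binding first —

      v = k_cat [E] [A][B] / (K_A K_B + K_B [A] + [A][B]);

* ping-pong bi-bi —

      v = k_cat [E] [A][B] / (K_A [B] + K_B [A] + [A][B]).

The three laws are distinguishable from the geometry of their
double-reciprocal (Lineweaver–Burk) families: ping-pong lines are parallel,
compulsory-order lines meet on the 1/v axis, and random-order lines meet at
(−1/K, (1 − alpha)/(k_cat [E])) off the axis.  The analytic slope/intercept
and intersection formulas below are the oracles the inference module checks
its regressions against.

Units: concentrations in μM, time in minutes, enzyme in nM, hence velocity
in nM product per minute.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticParameters",
    "Mechanism",
    "ReciprocalLine",
    "ParallelLinesError",
    "velocity",
    "velocity_random_re",
    "velocity_ping_pong",
    "velocity_ordered_re",
    "reciprocal_line_analytic",
    "intersection_point",
]


class Mechanism(enum.Enum):
    """Candidate bisubstrate mechanisms."""

    RANDOM_RAPID_EQUILIBRIUM = "random_rapid_equilibrium"
    ORDERED_RAPID_EQUILIBRIUM_A_FIRST = "ordered_rapid_equilibrium_a_first"
    PING_PONG = "ping_pong"

    @property
    def n_parameters(self) -> int:
        """Number of free kinetic parameters (enzyme concentration excluded)."""
        return 4 if self is Mechanism.RANDOM_RAPID_EQUILIBRIUM else 3


class ParallelLinesError(ValueError):
    """Raised when an intersection point is requested for parallel-line geometry."""


@dataclass(frozen=True)
class KineticParameters:
    """Parameter vector of the bisubstrate rate laws.

    Attributes
    ----------
    k_cat : float
        Turnover number, per minute.
    K_A : float
        Dissociation constant of the enzyme–donor binary complex, μM.
    K_B : float
        Dissociation constant of the enzyme–acceptor binary complex, μM.
    alpha : float
        Dimensionless cooperativity factor; ``alpha < 1`` means each substrate
        tightens the binding of the other in the ternary complex.
    enzyme_conc : float
        Total enzyme concentration, nM.
    """

    k_cat: float
    K_A: float
    K_B: float
    alpha: float
    enzyme_conc: float

    def __post_init__(self) -> None:
        for name in ("k_cat", "K_A", "K_B", "alpha", "enzyme_conc"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")

    @property
    def v_max(self) -> float:
        """Saturating velocity k_cat·[E], nM/min."""
        return self.k_cat * self.enzyme_conc


@dataclass(frozen=True)
class ReciprocalLine:
    """One line of a double-reciprocal family at a fixed co-substrate level.

    ``slope`` is in min·μM per nM product, ``intercept`` in min per nM product.
    ``n_points`` is the number of underlying (1/conc, 1/v) points; analytic
    lines report the minimum of 3.
    """

    fixed_cosubstrate_conc: float
    slope: float
    intercept: float
    slope_se: float = 0.0
    intercept_se: float = 0.0
    n_points: int = 3

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a reciprocal line needs at least 3 points")
        if self.slope_se < 0 or self.intercept_se < 0:
            raise ValueError("standard errors must be nonnegative")
        if not self.fixed_cosubstrate_conc > 0:
            raise ValueError("fixed co-substrate concentration must be positive")

    def y_at(self, x: float) -> float:
        return self.intercept + self.slope * x


def _validate_concs(a_conc, b_conc):
    a = np.asarray(a_conc, dtype=float)
    b = np.asarray(b_conc, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("concentrations must be finite")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("concentrations must be nonnegative")
    return a, b


def _ratio(num, den, scalar: bool):
    # both substrates appear in the numerator, so v -> 0 at a zero
    # concentration; the guard removes the 0/0 at the double-zero corner
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(num == 0.0, 0.0, num / np.where(den == 0.0, 1.0, den))
    return float(out) if scalar else out


def velocity_random_re(params: KineticParameters, a_conc, b_conc):
    """Initial velocity of the rapid-equilibrium random-order sequential law, nM/min."""
    a, b = _validate_concs(a_conc, b_conc)
    scalar = np.isscalar(a_conc) and np.isscalar(b_conc)
    p = params
    den = p.alpha * (p.K_A * p.K_B + p.K_A * b + p.K_B * a) + a * b
    return _ratio(p.v_max * a * b, den, scalar)


def velocity_ping_pong(params: KineticParameters, a_conc, b_conc):
    """Initial velocity of the ping-pong bi-bi law, nM/min.

    The cooperativity factor of ``params`` is ignored; a ping-pong enzyme never
    forms the ternary complex.
    """
    a, b = _validate_concs(a_conc, b_conc)
    scalar = np.isscalar(a_conc) and np.isscalar(b_conc)
    p = params
    den = p.K_A * b + p.K_B * a + a * b
    return _ratio(p.v_max * a * b, den, scalar)


def velocity_ordered_re(params: KineticParameters, a_conc, b_conc):
    """Initial velocity of the rapid-equilibrium compulsory-order (A first) law, nM/min.

    ``alpha`` is ignored: with a fixed binding order there is no independent
    ternary-complex factor.
    """
    a, b = _validate_concs(a_conc, b_conc)
    scalar = np.isscalar(a_conc) and np.isscalar(b_conc)
    p = params
    den = p.K_A * p.K_B + p.K_B * a + a * b
    return _ratio(p.v_max * a * b, den, scalar)


_VELOCITY = {
    Mechanism.RANDOM_RAPID_EQUILIBRIUM: velocity_random_re,
    Mechanism.PING_PONG: velocity_ping_pong,
    Mechanism.ORDERED_RAPID_EQUILIBRIUM_A_FIRST: velocity_ordered_re,
}


def velocity(mechanism: Mechanism, params: KineticParameters, a_conc, b_conc):
    """Dispatch to the rate law of ``mechanism``."""
    return _VELOCITY[Mechanism(mechanism)](params, a_conc, b_conc)


def reciprocal_line_analytic(
    mechanism: Mechanism,
    params: KineticParameters,
    fixed_conc: float,
    varying: str,
) -> ReciprocalLine:
    """Exact Lineweaver–Burk line 1/v vs 1/[varying substrate].

    Parameters
    ----------
    fixed_conc : float
        Concentration (μM) of the co-substrate held fixed.
    varying : {"A", "B"}
        Which substrate's reciprocal concentration forms the x axis.

    Returns
    -------
    ReciprocalLine
        With zero standard errors (the line is exact) and ``n_points = 3``.
    """
    if not (math.isfinite(fixed_conc) and fixed_conc > 0):
        raise ValueError("fixed_conc must be strictly positive")
    varying = varying.upper()
    if varying not in ("A", "B"):
        raise ValueError("varying must be 'A' or 'B'")
    p = params
    vm = p.v_max
    mech = Mechanism(mechanism)
    f = fixed_conc
    if mech is Mechanism.RANDOM_RAPID_EQUILIBRIUM:
        if varying == "B":
            slope = (p.alpha * p.K_B / vm) * (1 + p.K_A / f)
            intercept = (1 / vm) * (1 + p.alpha * p.K_A / f)
        else:
            slope = (p.alpha * p.K_A / vm) * (1 + p.K_B / f)
            intercept = (1 / vm) * (1 + p.alpha * p.K_B / f)
    elif mech is Mechanism.PING_PONG:
        if varying == "B":
            slope = p.K_B / vm
            intercept = (1 / vm) * (1 + p.K_A / f)
        else:
            slope = p.K_A / vm
            intercept = (1 / vm) * (1 + p.K_B / f)
    else:  # ordered, A first
        if varying == "B":
            slope = (p.K_B / vm) * (1 + p.K_A / f)
            intercept = 1 / vm
        else:
            slope = p.K_A * p.K_B / (vm * f)
            intercept = (1 / vm) * (1 + p.K_B / f)
    return ReciprocalLine(fixed_cosubstrate_conc=f, slope=slope, intercept=intercept)


def intersection_point(
    params: KineticParameters,
    varying: str,
    mechanism: Mechanism = Mechanism.RANDOM_RAPID_EQUILIBRIUM,
) -> tuple[float, float]:
    """Common intersection of a double-reciprocal line family.

    For the random-order law the whole family at distinct fixed co-substrate
    levels passes through ``(-1/K, (1 - alpha)/(k_cat [E]))`` where K is the
    binary dissociation constant of the varying substrate; alpha = 1 places the
    point on the x axis, alpha < 1 above it.  For the compulsory-order law the
    point lies on the 1/v axis when B varies.  Ping-pong families are parallel
    and have no finite intersection.
    """
    varying = varying.upper()
    if varying not in ("A", "B"):
        raise ValueError("varying must be 'A' or 'B'")
    mech = Mechanism(mechanism)
    p = params
    vm = p.v_max
    if mech is Mechanism.PING_PONG:
        raise ParallelLinesError("ping-pong reciprocal lines are parallel; no finite intersection")
    if mech is Mechanism.RANDOM_RAPID_EQUILIBRIUM:
        k = p.K_B if varying == "B" else p.K_A
        return (-1.0 / k, (1.0 - p.alpha) / vm)
    # ordered, A first: varying B -> on the 1/v axis; varying A -> (-1/K_A, 1/vm)
    if varying == "B":
        return (0.0, 1.0 / vm)
    return (-1.0 / p.K_A, 1.0 / vm)
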