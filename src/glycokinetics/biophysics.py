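"""SPR sensorgram processing, 1:1 affinity fits, and SEC molecular-weight calibration.

Processing follows the standard Biacore-style chain: double referencing
(active − reference, minus the same difference for the nearest blank buffer
cycle), solvent correction through a calibration map keyed on the
reference-cell bulk excess, equilibrium-response extraction from the tail of
the association phase, and then either a steady-state Langmuir isotherm fit
``Req = Rmax·C/(KD + C) + offset`` or a global 1:1 kinetic fit with a single
shared Rmax.  A weak binder that does not approach saturation at the top
concentration yields a poorly constrained KD; the steady-state fit flags
that case instead of hiding it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data import Sensorgram

__all__ = [
    "SteadyStateAffinityFit",
    "Kinetic1to1Fit",
    "SECCalibration",
    "MWEstimate",
    "ReqPoint",
    "double_reference",
    "solvent_correct",
    "extract_req",
    "fit_steady_state",
    "fit_kinetic_1to1",
    "theoretical_rmax",
    "fit_sec_calibration",
    "estimate_mw",
]


@dataclass(frozen=True)
class ReqPoint:
    """Equilibrium response at one analyte concentration."""

    conc: float  # μM
    req: float  # RU
    nonequilibrium: bool = False  # response still rising across the window


@dataclass(frozen=True)
class SteadyStateAffinityFit:
    """Steady-state 1:1 Langmuir affinity fit."""

    kd: float  # μM
    rmax: float  # RU
    offset: float  # RU
    kd_se: float
    rmax_se: float
    offset_se: float
    saturation_at_top: float  # Req(top)/Rmax
    n_concs: int
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.rmax <= 0:
            raise ValueError("kd and rmax must be positive")
        if not (0.0 <= self.saturation_at_top <= 1.0):
            raise ValueError("saturation_at_top must lie in [0, 1]")


@dataclass(frozen=True)
class Kinetic1to1Fit:
    """Global 1:1 kinetic fit with a single shared Rmax."""

    kon: float  # per M per s
    koff: float  # per s
    rmax: float  # RU
    kd_kinetic: float  # μM, = koff/kon
    kon_se: float
    koff_se: float
    rmax_se: float
    converged: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.converged and "kon_unidentifiable" not in self.flags:
            if not (self.kon > 0 and self.koff > 0):
                raise ValueError("kon and koff must be positive")
            implied = self.koff / self.kon * 1e6
            if abs(implied - self.kd_kinetic) > 1e-12 * max(implied, self.kd_kinetic):
                raise ValueError("kd_kinetic inconsistent with koff/kon")


@dataclass(frozen=True)
class SECCalibration:
    """Log-linear gel-filtration calibration: log10(MW kDa) = intercept + slope·V."""

    standards: tuple[tuple[float, float], ...]  # (MW kDa, elution ml)
    intercept: float
    slope: float
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.standards) < 3:
            raise ValueError("need >= 3 standards")
        if self.slope >= 0:
            raise ValueError("calibration slope must be negative")


@dataclass(frozen=True)
class MWEstimate:
    mw_kda: float
    extrapolated: bool


# ---------------------------------------------------------------------------
# sensorgram processing


def _align(base: Sensorgram, other: Sensorgram, tolerance: float) -> np.ndarray:
    """Other's response on base's time grid (linear interpolation)."""
    t0 = max(base.times[0], other.times[0])
    t1 = min(base.times[-1], other.times[-1])
    if t1 <= t0:
        raise ValueError("sensorgram time ranges do not overlap")
    if base.times[0] < other.times[0] - tolerance or base.times[-1] > other.times[-1] + tolerance:
        raise ValueError("time bases differ beyond the interpolation tolerance")
    if other.times.shape == base.times.shape and np.allclose(other.times, base.times):
        return other.response
    return np.interp(base.times, other.times, other.response)


def double_reference(
    active: Sensorgram,
    reference: Sensorgram,
    blank_active: Sensorgram,
    blank_reference: Sensorgram | None = None,
    tolerance: float = 1.0,
) -> Sensorgram:
    """Double referencing: active − reference − (blank_active − blank_reference).

    Removes the bulk refractive-index pulse (shared by active and reference
    cells) and each cell's baseline drift (shared between analyte and blank
    cycles) exactly under the additive signal model.  ``blank_reference`` may
    be omitted when the blank trace has already been referenced.

    The reference cell's bulk excess during the injection is recorded on the
    output as ``ref_excess``, the key for solvent correction.
    """
    ref = _align(active, reference, tolerance)
    blank = _align(active, blank_active, tolerance)
    if blank_reference is not None:
        blank = blank - _align(active, blank_reference, tolerance)
    corrected = active.response - ref - blank
    # half-open injection window: the sample at injection_stop is already post-pulse
    inj = (active.times >= active.injection_start) & (active.times < active.injection_stop)
    pre = active.times < active.injection_start
    baseline = float(ref[pre].mean()) if pre.any() else 0.0
    ref_excess = float(ref[inj].mean()) - baseline
    return active.replace_response(corrected, ref_excess=ref_excess)


def solvent_correct(
    corrected: Sensorgram,
    calibration: tuple[np.ndarray, np.ndarray],
) -> Sensorgram:
    """Subtract the solvent (excluded-volume) correction.

    ``calibration`` maps reference-cell bulk excess (RU) to the correction (RU)
    and must be monotone in its key; the correction for this cycle's
    ``ref_excess`` is interpolated and subtracted from the whole trace.  A zero
    map is the identity.  Keys outside the calibrated domain trigger an
    extrapolation warning (the edge value is used).
    """
    excess_grid = np.asarray(calibration[0], dtype=float)
    corr_grid = np.asarray(calibration[1], dtype=float)
    if excess_grid.size != corr_grid.size or excess_grid.size < 1:
        raise ValueError("calibration arrays must be non-empty and equal-length")
    if excess_grid.size > 1 and np.any(np.diff(excess_grid) <= 0):
        raise ValueError("calibration keys must be strictly increasing")
    excess = corrected.ref_excess if corrected.ref_excess is not None else 0.0
    if excess < excess_grid[0] or excess > excess_grid[-1]:
        warnings.warn(
            f"reference excess {excess:.3g} RU outside the solvent-calibration domain "
            f"[{excess_grid[0]:.3g}, {excess_grid[-1]:.3g}]; edge value used",
            stacklevel=2,
        )
    correction = float(np.interp(excess, excess_grid, corr_grid))
    return corrected.replace_response(corrected.response - correction)


def extract_req(corrected: Sensorgram, window: float = 0.10) -> ReqPoint:
    """Equilibrium response: mean over the final ``window`` fraction of association.

    Flags the point as non-equilibrium when the response still rises by more
    than 5% (of its mean) across the window.
    """
    if not (0.0 < window <= 1.0):
        raise ValueError("window must be in (0, 1]")
    t_all = corrected.times
    mask = (t_all >= corrected.injection_start) & (t_all < corrected.injection_stop)
    if mask.sum() < 5:
        raise ValueError("association phase must contain >= 5 samples")
    t = corrected.times[mask]
    r = corrected.response[mask]
    t_start = corrected.injection_stop - window * (corrected.injection_stop - corrected.injection_start)
    tail = t >= t_start
    if tail.sum() < 2:
        tail = np.zeros_like(t, dtype=bool)
        tail[-2:] = True
    req = float(r[tail].mean())
    slope = float(np.polyfit(t[tail], r[tail], 1)[0])
    rise = slope * (t[tail][-1] - t[tail][0])
    noneq = abs(req) > 0 and rise / max(abs(req), 1e-12) > 0.05
    return ReqPoint(conc=corrected.analyte_conc, req=req, nonequilibrium=bool(noneq))


# ---------------------------------------------------------------------------
# affinity fits


def fit_steady_state(
    points: list[tuple[float, float]] | list[ReqPoint],
    fit_offset: bool = True,
) -> SteadyStateAffinityFit:
    """Least-squares fit of the 1:1 steady-state isotherm Req = Rmax·C/(KD+C) + offset.

    Rmax floats freely; the additive offset (bulk refractive-index residual)
    is fitted by default, seeded at 0.  When the top concentration reaches
    less than half-saturation (Req(top)/Rmax < 0.5) a ``nonsaturation``
    warning is attached: the KD is then poorly constrained, as for very weak
    binders whose affinity "could not be measured reliably".
    """
    concs = np.array([p.conc if isinstance(p, ReqPoint) else p[0] for p in points], dtype=float)
    reqs = np.array([p.req if isinstance(p, ReqPoint) else p[1] for p in points], dtype=float)
    if np.unique(concs).size < 3:
        raise ValueError("steady-state fit needs >= 3 distinct concentrations")
    top = float(concs.max())
    r_top = float(reqs[np.argmax(concs)])
    r_scale = max(abs(r_top), 1e-6)

    def model(theta: np.ndarray) -> np.ndarray:
        kd, rmax = np.exp(theta[:2])
        offset = theta[2] if fit_offset else 0.0
        return rmax * concs / (kd + concs) + offset

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(theta) - reqs

    best = None
    for kd0 in (top * 0.1, top, top * 10.0):
        theta0 = [math.log(kd0), math.log(2.0 * r_scale)]
        if fit_offset:
            theta0.append(0.0)
        sol = optimize.least_squares(residuals, theta0, method="lm", ftol=1e-14, xtol=1e-14, gtol=1e-14)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:  # pragma: no cover - lm on a smooth model
        raise RuntimeError("steady-state fit failed from all starts")
    kd, rmax = (float(x) for x in np.exp(best.x[:2]))
    offset = float(best.x[2]) if fit_offset else 0.0
    n = concs.size
    k = 3 if fit_offset else 2
    rss = float(2.0 * best.cost)
    s2 = rss / max(n - k, 1)
    cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
    # delta method for the log-parameterized kd and rmax
    nat = np.array([kd, rmax] + ([1.0] if fit_offset else []))
    ses = np.sqrt(np.clip(np.diag(cov), 0, None)) * nat
    saturation = top / (kd + top)
    warns: list[str] = []
    if saturation < 0.5:
        warns.append("nonsaturation: top concentration below half-saturation; KD poorly constrained")
    if kd < concs.min() / 100.0:
        warns.append("kd_at_lower_boundary: fitted KD far below the measured range")
    return SteadyStateAffinityFit(
        kd=kd,
        rmax=rmax,
        offset=offset,
        kd_se=float(ses[0]),
        rmax_se=float(ses[1]),
        offset_se=float(ses[2]) if fit_offset else 0.0,
        saturation_at_top=min(saturation, 1.0),
        n_concs=int(np.unique(concs).size),
        warnings=tuple(warns),
    )


def _kinetic_model(
    theta: np.ndarray, gram: Sensorgram
) -> np.ndarray:
    kon, koff, rmax = np.exp(theta)
    c_molar = gram.analyte_conc * 1e-6
    kobs = kon * c_molar + koff
    req = rmax * kon * c_molar / kobs
    t = gram.times
    out = np.zeros_like(t)
    assoc = (t >= gram.injection_start) & (t <= gram.injection_stop)
    out[assoc] = req * (1.0 - np.exp(-kobs * (t[assoc] - gram.injection_start)))
    t_a = gram.injection_stop - gram.injection_start
    r_stop = req * (1.0 - np.exp(-kobs * t_a))
    dissoc = t > gram.injection_stop
    out[dissoc] = r_stop * np.exp(-koff * (t[dissoc] - gram.injection_stop))
    return out


def fit_kinetic_1to1(family: list[Sensorgram]) -> Kinetic1to1Fit:
    """Global 1:1 kinetic fit across a corrected sensorgram family.

    One (kon, koff, Rmax) triple is shared by every concentration; parameters
    are log-transformed.  With dissociation-only input (no samples inside the
    injection window) only koff is identifiable: it is recovered from the
    decay and the on-rate is flagged.
    """
    cycles = [g for g in family if g.analyte_conc > 0]
    if len({g.analyte_conc for g in cycles}) < 2:
        raise ValueError("kinetic fit needs >= 2 distinct positive concentrations")
    has_assoc = any(g.association_mask().sum() >= 2 for g in cycles)
    if not has_assoc:
        koffs = []
        for g in cycles:
            dissoc = g.times > g.injection_stop
            r = g.response[dissoc]
            t = g.times[dissoc]
            pos = r > 0
            if pos.sum() >= 2:
                koffs.append(-float(np.polyfit(t[pos], np.log(r[pos]), 1)[0]))
        koff = float(np.mean(koffs))
        return Kinetic1to1Fit(
            kon=math.nan, koff=koff, rmax=math.nan, kd_kinetic=math.nan,
            kon_se=math.nan, koff_se=float(np.std(koffs)), rmax_se=math.nan,
            converged=True, flags=("kon_unidentifiable",),
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return np.concatenate([_kinetic_model(theta, g) - g.response for g in cycles])

    top = max(g.analyte_conc for g in cycles)
    r_top = max(float(np.max(np.abs(g.response))) for g in cycles)
    # crude off-rate start from the top cycle's decay half-life
    koff0 = 0.1
    best = None
    for kd0_um in (top * 0.1, top, top * 10.0):
        kon0 = koff0 / (kd0_um * 1e-6)
        theta0 = np.log([kon0, koff0, max(2.0 * r_top, 1e-3)])
        sol = optimize.least_squares(residuals, theta0, method="lm", ftol=1e-14, xtol=1e-14, gtol=1e-14)
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return Kinetic1to1Fit(
            kon=math.nan, koff=math.nan, rmax=math.nan, kd_kinetic=math.nan,
            kon_se=math.nan, koff_se=math.nan, rmax_se=math.nan,
            converged=False, flags=("nonconvergent",),
        )
    kon, koff, rmax = (float(x) for x in np.exp(best.x))
    n = sum(g.times.size for g in cycles)
    s2 = 2.0 * best.cost / max(n - 3, 1)
    cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None)) * np.array([kon, koff, rmax])
    return Kinetic1to1Fit(
        kon=kon, koff=koff, rmax=rmax, kd_kinetic=koff / kon * 1e6,
        kon_se=float(ses[0]), koff_se=float(ses[1]), rmax_se=float(ses[2]),
        converged=True,
    )


def theoretical_rmax(
    ligand_density: float, mw_ligand: float, mw_analyte: float, valency: int = 1
) -> float:
    """Mass-transport-free Rmax bound: density · (MW_analyte/MW_ligand) · valency."""
    if ligand_density <= 0 or mw_analyte <= 0 or valency <= 0:
        raise ValueError("all arguments must be positive")
    if mw_ligand <= 0:
        raise ValueError("mw_ligand must be positive")
    return ligand_density * (mw_analyte / mw_ligand) * valency


# ---------------------------------------------------------------------------
# SEC calibration


def fit_sec_calibration(standards: list[tuple[float, float]]) -> SECCalibration:
    """OLS of log10(MW kDa) on elution volume over the calibration standards."""
    if len(standards) < 3:
        raise ValueError("need >= 3 standards")
    mw = np.array([s[0] for s in standards], dtype=float)
    vol = np.array([s[1] for s in standards], dtype=float)
    if np.unique(vol).size < len(standards):
        raise ValueError("standards must have distinct elution volumes")
    res = stats.linregress(vol, np.log10(mw))
    if res.slope >= 0:
        raise ValueError("positive calibration slope: larger species must elute earlier")
    return SECCalibration(
        standards=tuple((float(m), float(v)) for m, v in standards),
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=min(float(res.rvalue**2), 1.0),
    )


def estimate_mw(elution: float, calibration: SECCalibration) -> MWEstimate:
    """Apparent molecular weight (kDa) from an elution volume; flags extrapolation."""
    vols = [v for _, v in calibration.standards]
    extrapolated = not (min(vols) <= elution <= max(vols))
    mw = 10.0 ** (calibration.intercept + calibration.slope * elution)
    return MWEstimate(mw_kda=float(mw), extrapolated=extrapolated)
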