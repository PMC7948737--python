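"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study's wet-lab assays: luminescent (UDP-Glo style)
activity plates read against a UDP standard curve, the printed 5×5
donor/acceptor concentration grid at 1.25 nM enzyme, 1:1 Langmuir SPR
sensorgram families on the printed 5-point 1:3 dilution series, and a
size-exclusion calibration.  Every generator takes an explicit
:class:`~glycokinetics.data.NoiseSpec`; with zero noise each reproduces its
closed-form model exactly, which the test suite leans on heavily.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .data import NoiseSpec, ProgressCurve, Sensorgram, StandardCurveData, VelocityDataset, VelocityObservation
from .rate_laws import KineticParameters, Mechanism, velocity, velocity_random_re

__all__ = [
    "DONOR_LEVELS_UM",
    "ACCEPTOR_LEVELS_UM",
    "REPORTED_PARAMS",
    "SPR_SERIES_UM",
    "SEC_STANDARDS",
    "simulate_velocity_dataset",
    "simulate_progress_curves",
    "simulate_standard_curve",
    "simulate_sensorgram_family",
    "simulate_sec_elution",
]

# The published experimental design: donor (UDP-GlcNAc) and acceptor (LacNAc)
# levels in μM, enzyme at 1.25 nM, and the reported best-fit constants.
DONOR_LEVELS_UM = (1000.0, 500.0, 250.0, 125.0, 62.0)
ACCEPTOR_LEVELS_UM = (25000.0, 12500.0, 6250.0, 3120.0, 1560.0)
REPORTED_PARAMS = KineticParameters(k_cat=35.8, K_A=216.0, K_B=8990.0, alpha=0.24, enzyme_conc=1.25)

# 5-point 1:3 dilution series topping at 200 μM, in μM.
SPR_SERIES_UM = (200.0, 66.7, 22.2, 7.41, 2.47)

# Gel-filtration standards: (name, MW kDa).
SEC_STANDARDS = (
    ("thyroglobulin", 670.0),
    ("gamma-globulin", 158.0),
    ("ovalbumin", 44.0),
    ("myoglobin", 17.0),
    ("vitamin B12", 1.35),
)


def simulate_velocity_dataset(
    params: KineticParameters,
    a_levels: Sequence[float] = DONOR_LEVELS_UM,
    b_levels: Sequence[float] = ACCEPTOR_LEVELS_UM,
    replicates: int = 3,
    noise: NoiseSpec = NoiseSpec(),
    mechanism: Mechanism = Mechanism.RANDOM_RAPID_EQUILIBRIUM,
) -> VelocityDataset:
    """Full-factorial initial-velocity table with multiplicative noise.

    Each observation is ``v_model × (1 + ε) + η`` with ``ε ~ N(0, cv²)`` and
    ``η ~ N(0, additive_sd²)``; identical seeds give bit-identical datasets.
    """
    a_levels = [float(x) for x in a_levels]
    b_levels = [float(x) for x in b_levels]
    if not a_levels or not b_levels:
        raise ValueError("substrate level lists must be non-empty")
    if any(x <= 0 for x in a_levels + b_levels):
        raise ValueError("substrate levels must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = noise.rng()
    a_grid, b_grid = [], []
    for a in a_levels:
        for b in b_levels:
            for _ in range(replicates):
                a_grid.append(a)
                b_grid.append(b)
    a_arr = np.array(a_grid)
    b_arr = np.array(b_grid)
    v_exact = velocity(mechanism, params, a_arr, b_arr)
    v_noisy = noise.apply(v_exact, rng)
    obs = []
    idx = 0
    for a in a_levels:
        for b in b_levels:
            for r in range(replicates):
                obs.append(
                    VelocityObservation(
                        a_conc=a,
                        b_conc=b,
                        velocity=float(v_noisy[idx]),
                        well_id=f"A{a:g}_B{b:g}_r{r + 1}",
                    )
                )
                idx += 1
    return VelocityDataset(observations=tuple(obs), enzyme_conc=params.enzyme_conc)


def _integrate_product(
    params: KineticParameters,
    a0: float,
    b0: float,
    times: np.ndarray,
    max_step: float,
) -> np.ndarray:
    """Product concentration P(t) in μM under 1:1 stoichiometric depletion.

    dP/dt = v(a0 − P, b0 − P) with v in nM/min, hence the 1e-3 factor.  Fixed
    step classical Runge–Kutta; steps subdivide the caller's sample intervals
    so the result depends only on the requested times.  P is clamped to
    [0, min(a0, b0)] (conservation).
    """
    p_cap = min(a0, b0)
    vmax = params.v_max * 1e-3  # μM/min

    def rate(p: float) -> float:
        if p >= p_cap:
            return 0.0
        return velocity_random_re(params, a0 - p, b0 - p) * 1e-3

    out = np.empty(times.size)
    out[0] = 0.0
    p = 0.0
    for i in range(1, times.size):
        span = times[i] - times[i - 1]
        n_sub = max(1, math.ceil(span / max_step))
        h = span / n_sub
        for _ in range(n_sub):
            k1 = rate(p)
            k2 = rate(p + 0.5 * h * k1)
            k3 = rate(p + 0.5 * h * k2)
            k4 = rate(p + h * k3)
            p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if p > p_cap:
                p = p_cap
        out[i] = p
    return out


def simulate_progress_curves(
    params: KineticParameters,
    a0: float,
    b0: float,
    times: Sequence[float],
    rlu_per_uM: float = 1000.0,
    background: float = 50.0,
    noise: NoiseSpec = NoiseSpec(),
    well_id: str = "",
    max_step: float = 0.1,
) -> ProgressCurve:
    """Luminescent progress curve with substrate depletion.

    The random-order rate law is integrated with both substrates depleting
    stoichiometrically 1:1 with product (no product inhibition); the UDP
    product is read out as ``background + rlu_per_uM · P(t)`` plus noise.
    """
    if not (a0 > 0 and b0 > 0):
        raise ValueError("initial substrate concentrations must be positive")
    if rlu_per_uM < 0:
        raise ValueError("rlu_per_uM must be nonnegative")
    t = np.asarray(times, dtype=float)
    if t[0] != 0.0:
        raise ValueError("times must start at 0")
    product = _integrate_product(params, a0, b0, t, max_step=max_step)
    signal = background + rlu_per_uM * product
    signal = noise.apply(signal, noise.rng())
    return ProgressCurve(
        times=t, signal=signal, a0=a0, b0=b0, enzyme_conc=params.enzyme_conc, well_id=well_id
    )


def simulate_standard_curve(
    udp_concs: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    rlu_per_uM: float = 1000.0,
    background: float = 50.0,
    noise: NoiseSpec = NoiseSpec(),
    replicates: int = 2,
) -> StandardCurveData:
    """UDP standard curve: a straight line ``background + rlu_per_uM · c`` plus noise."""
    concs = np.asarray(udp_concs, dtype=float)
    if np.any(concs < 0):
        raise ValueError("UDP concentrations must be nonnegative")
    rng = noise.rng()
    all_concs = np.tile(concs, replicates)
    rep_ids = np.repeat(np.arange(1, replicates + 1), concs.size)
    signal = noise.apply(background + rlu_per_uM * all_concs, rng)
    return StandardCurveData(udp_concs=all_concs, signals=signal, replicates=rep_ids)


def _one_cycle(
    times: np.ndarray,
    binding: np.ndarray,
    bulk: float,
    drift_slope: float,
    inj_mask: np.ndarray,
    conc: float,
    role: str,
    t0: float,
    t1: float,
    cycle_id: str,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> Sensorgram:
    resp = binding + drift_slope * times
    resp = resp + np.where(inj_mask, bulk, 0.0)
    resp = noise.apply(resp, rng)
    return Sensorgram(
        times=times,
        response=resp,
        analyte_conc=conc,
        role=role,
        injection_start=t0,
        injection_stop=t1,
        cycle_id=cycle_id,
    )


def simulate_sensorgram_family(
    kd: float,
    kon: float,
    rmax: float,
    conc_series: Sequence[float] = SPR_SERIES_UM,
    t_assoc: float = 60.0,
    t_dissoc: float = 120.0,
    bulk_ri: float = 5.0,
    drift: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
    sample_hz: float = 10.0,
    baseline_s: float = 10.0,
    n_blanks: int = 1,
    solvent_mismatch: float = 0.0,
) -> list[Sensorgram]:
    """1:1 Langmuir sensorgram family with references and blank cycles.

    Parameters
    ----------
    kd : float
        Equilibrium dissociation constant, μM.
    kon : float
        Association rate, per M per s; ``koff = kon · kd`` (after unit
        conversion) fixes the off-rate.
    rmax : float
        Saturating response, RU.
    bulk_ri : float
        Bulk refractive-index square pulse during the injection, RU; appears in
        active and reference cells alike.
    drift : float
        Baseline drift slope of the active cell, RU/s; the reference cell
        drifts at half that rate, so drift removal genuinely requires the blank
        cycles of double referencing.
    solvent_mismatch : float
        Extra bulk RU present in the active cell only (DMSO excluded-volume
        mismatch); survives double referencing and is the target of solvent
        correction, keyed on the reference-cell excess ``bulk_ri``.

    Returns
    -------
    list of Sensorgram
        For each concentration an active and a reference cycle, plus
        ``n_blanks`` zero-concentration blank cycle pairs.
    """
    if t_assoc <= 0:
        raise ValueError("t_assoc must be positive")
    if kd <= 0 or kon <= 0 or rmax <= 0:
        raise ValueError("kd, kon, rmax must be positive")
    koff = kon * kd * 1e-6  # per s; kd in μM -> M
    t0 = baseline_s
    t1 = baseline_s + t_assoc
    t_end = t1 + t_dissoc
    times = np.arange(0.0, t_end + 0.5 / sample_hz, 1.0 / sample_hz)
    inj_mask = (times >= t0) & (times < t1)
    rng = noise.rng()
    out: list[Sensorgram] = []
    ref_drift = 0.5 * drift

    def binding_curve(conc: float) -> np.ndarray:
        if conc == 0.0:
            return np.zeros_like(times)
        kobs = kon * conc * 1e-6 + koff
        req = rmax * conc / (kd + conc)
        curve = np.zeros_like(times)
        assoc = inj_mask
        curve[assoc] = req * (1.0 - np.exp(-kobs * (times[assoc] - t0)))
        r_stop = req * (1.0 - np.exp(-kobs * t_assoc))
        dissoc = times >= t1
        curve[dissoc] = r_stop * np.exp(-koff * (times[dissoc] - t1))
        return curve

    for i, conc in enumerate(conc_series):
        cid = f"cycle{i + 1}"
        out.append(
            _one_cycle(times, binding_curve(float(conc)) + np.where(inj_mask, solvent_mismatch, 0.0),
                       bulk_ri, drift, inj_mask, float(conc), "active", t0, t1, cid, noise, rng)
        )
        out.append(
            _one_cycle(times, np.zeros_like(times), bulk_ri, ref_drift, inj_mask,
                       float(conc), "reference", t0, t1, cid, noise, rng)
        )
    for j in range(n_blanks):
        cid = f"blank{j + 1}"
        out.append(
            _one_cycle(times, np.zeros_like(times), 0.0, drift, inj_mask,
                       0.0, "active", t0, t1, cid, noise, rng)
        )
        out.append(
            _one_cycle(times, np.zeros_like(times), 0.0, ref_drift, inj_mask,
                       0.0, "reference", t0, t1, cid, noise, rng)
        )
    return out


def simulate_sec_elution(
    calibration_truth: tuple[float, float],
    mw: float,
    noise: NoiseSpec = NoiseSpec(),
) -> float:
    """Elution volume (ml) of a species of mass ``mw`` (kDa).

    ``calibration_truth`` is the (intercept, slope) of the column's
    log10(MW kDa) vs elution-volume relation; slope must be negative (larger
    species elute earlier).
    """
    intercept, slope = calibration_truth
    if slope >= 0:
        raise ValueError("calibration slope must be negative")
    if mw <= 0:
        raise ValueError("mw must be positive")
    volume = (math.log10(mw) - intercept) / slope
    rng = noise.rng()
    return float(noise.apply(np.array([volume]), rng)[0])
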