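"""Mechanism discrimination and global fitting of bisubstrate rate laws.

Two complementary routes mirror how bisubstrate mechanisms are argued in
practice:

* **Double-reciprocal diagnostics** — per-fixed-level OLS lines in
  (1/conc, 1/v) space and extra-sum-of-squares F-tests of the two geometric
  signatures: a common slope (parallel lines ⇒ ping-pong) and a common
  intercept (y-axis intersection ⇒ compulsory order).  These plots are
  diagnostics only; no parameter estimate is taken from reciprocal space,
  where the error structure is badly distorted.

* **Global nonlinear fitting** — all observations fitted at once in velocity
  space to each candidate rate law, parameters log-transformed to enforce
  positivity, deterministic multi-start to dodge local minima, AICc for the
  three-way non-nested model comparison, and case-resampling bootstrap
  (stratified by grid cell) for uncertainty intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .data import VelocityDataset
from .rate_laws import KineticParameters, Mechanism, ReciprocalLine, velocity

__all__ = [
    "DiagnosticResult",
    "FitOptions",
    "GlobalFitResult",
    "ModelComparison",
    "BootstrapResult",
    "CooperativityFold",
    "fit_reciprocal_lines",
    "test_parallel_vs_intersecting",
    "test_yaxis_intersection",
    "fit_global",
    "compare_mechanisms",
    "bootstrap_uncertainty",
    "cooperativity_fold",
    "aicc",
]


@dataclass(frozen=True)
class DiagnosticResult:
    """Outcome of one extra-sum-of-squares F-test on reciprocal-space points."""

    test_name: str
    statistic: float
    dof: tuple[int, int]
    p_value: float
    decision: str
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("F statistic must be nonnegative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class FitOptions:
    """Controls for the global fit.

    The multi-start grid is deterministic: k_cat seeded from the largest
    observed v/[E] scaled by ``kcat_factors``; each K from the geometric
    mid-range of its substrate's levels scaled by ``k_factors``; alpha from
    ``alpha_starts`` (random-order law only).
    """

    kcat_factors: tuple[float, ...] = (0.5, 1.0, 2.0)
    k_factors: tuple[float, ...] = (0.2, 1.0, 5.0)
    alpha_starts: tuple[float, ...] = (0.1, 1.0, 10.0)
    ftol: float = 1e-14
    xtol: float = 1e-14
    gtol: float = 1e-14
    max_nfev: int | None = None
    weights: np.ndarray | None = None
    p_threshold: float = 0.05


@dataclass(frozen=True)
class GlobalFitResult:
    """Global nonlinear fit of one mechanism's rate law."""

    mechanism: Mechanism
    estimates: KineticParameters  # enzyme_conc fixed, not fitted
    standard_errors: dict[str, float]
    covariance: np.ndarray  # natural scale, fitted parameters only
    param_names: tuple[str, ...]
    rss: float
    n_obs: int
    aicc: float
    converged: bool
    n_restarts_used: int

    def __post_init__(self) -> None:
        if self.converged:
            if any(se < 0 for se in self.standard_errors.values()):
                raise ValueError("standard errors must be nonnegative")
            if not math.isfinite(self.aicc):
                raise ValueError("aicc must be finite for a converged fit")


@dataclass(frozen=True)
class ModelComparison:
    """AICc comparison of the three candidate mechanisms."""

    results: dict[Mechanism, GlobalFitResult]
    delta_aicc: dict[Mechanism, float]
    selected: Mechanism
    diagnostics: tuple[DiagnosticResult, ...] = ()

    def __post_init__(self) -> None:
        if self.delta_aicc[self.selected] != 0.0:
            raise ValueError("selected mechanism must have delta_aicc = 0")


@dataclass(frozen=True)
class BootstrapResult:
    """Stratified case-resampling bootstrap percentile intervals."""

    intervals: dict[str, tuple[float, float]]
    n_boot: int
    n_failures: int
    seed: int
    samples: np.ndarray = field(repr=False, default=None)  # (n_ok, k)


class CooperativityFold(NamedTuple):
    """Binary-to-ternary affinity enhancement 1/alpha, with a rounded reading."""

    fold: float
    rounded: int


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike score n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        return math.inf
    rss = max(rss, 1e-300)  # a perfect fit is still comparable
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# reciprocal-space diagnostics


def fit_reciprocal_lines(data: VelocityDataset, varying: str = "B") -> list[ReciprocalLine]:
    """One OLS line per fixed co-substrate level in (1/conc, 1/v) space.

    Observations with nonpositive velocity are excluded (with a warning): they
    have no reciprocal.  Lines need >= 3 usable points; at least two usable
    lines are required.
    """
    varying = varying.upper()
    if varying not in ("A", "B"):
        raise ValueError("varying must be 'A' or 'B'")
    x_conc = data.b if varying == "B" else data.a
    fixed_conc = data.a if varying == "B" else data.b
    v = data.v
    usable = v > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} observation(s) with nonpositive velocity excluded from "
            "reciprocal diagnostics",
            stacklevel=2,
        )
    lines: list[ReciprocalLine] = []
    for level in np.unique(fixed_conc[usable]):
        sel = usable & (fixed_conc == level)
        if sel.sum() < 3:
            warnings.warn(
                f"fixed level {level:g} uM has {int(sel.sum())} usable points (<3); skipped",
                stacklevel=2,
            )
            continue
        res = stats.linregress(1.0 / x_conc[sel], 1.0 / v[sel])
        lines.append(
            ReciprocalLine(
                fixed_cosubstrate_conc=float(level),
                slope=float(res.slope),
                intercept=float(res.intercept),
                slope_se=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
                intercept_se=float(res.intercept_stderr)
                if np.isfinite(res.intercept_stderr)
                else 0.0,
                n_points=int(sel.sum()),
            )
        )
    if len(lines) < 2:
        raise ValueError("need >= 2 usable reciprocal lines for diagnostics")
    return lines


def _reciprocal_points(data: VelocityDataset, varying: str):
    varying = varying.upper()
    x_conc = data.b if varying == "B" else data.a
    fixed_conc = data.a if varying == "B" else data.b
    usable = data.v > 0
    x = 1.0 / x_conc[usable]
    y = 1.0 / data.v[usable]
    groups = fixed_conc[usable]
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need >= 2 fixed co-substrate levels")
    for level in levels:
        if (groups == level).sum() < 3:
            raise ValueError(f"fixed level {level:g} uM has < 3 usable points")
    return x, y, groups, levels, int((~usable).sum())


def _group_ols_rss(x, y, groups, levels) -> float:
    rss = 0.0
    for level in levels:
        sel = groups == level
        slope, intercept = np.polyfit(x[sel], y[sel], 1)
        resid = y[sel] - (intercept + slope * x[sel])
        rss += float(resid @ resid)
    return rss


def _constrained_rss(x, y, groups, levels, shared: str) -> float:
    """RSS of the reduced model: shared slope or shared intercept across groups."""
    n = x.size
    m = levels.size
    design = np.zeros((n, m + 1))
    if shared == "slope":
        design[:, 0] = x
        for j, level in enumerate(levels):
            design[groups == level, 1 + j] = 1.0
    else:  # shared intercept
        design[:, 0] = 1.0
        for j, level in enumerate(levels):
            sel = groups == level
            design[sel, 1 + j] = x[sel]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def _lines_degenerate(x, y, groups, levels) -> bool:
    """True when every group traces the same line (nothing to discriminate)."""
    params = []
    for level in levels:
        sel = groups == level
        params.append(np.polyfit(x[sel], y[sel], 1))
    params = np.array(params)
    scale = np.abs(params).max(axis=0) + 1e-300
    return bool(np.all(np.ptp(params, axis=0) / scale < 1e-9))


def _extra_ss_test(
    data: VelocityDataset,
    varying: str,
    shared: str,
    test_name: str,
    accept_decision: str,
    reject_decision: str,
    p_threshold: float,
) -> DiagnosticResult:
    x, y, groups, levels, n_excluded = _reciprocal_points(data, varying)
    n, m = x.size, levels.size
    df_full = n - 2 * m
    if df_full <= 0:
        raise ValueError("not enough points for the free-lines model")
    if _lines_degenerate(x, y, groups, levels):
        return DiagnosticResult(test_name, 0.0, (m - 1, df_full), 1.0, "degenerate", n_excluded)
    rss_full = _group_ols_rss(x, y, groups, levels)
    rss_red = _constrained_rss(x, y, groups, levels, shared)
    df_extra = m - 1
    scale = float(y @ y)
    tiny = 1e-24 * max(scale, 1e-300)
    if rss_full <= tiny:
        # exact data: either the reduced model also fits exactly (constraint
        # holds) or it cannot (constraint violated with certainty)
        if rss_red - rss_full <= tiny:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
    else:
        f_stat = ((rss_red - rss_full) / df_extra) / (rss_full / df_full)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df_extra, df_full))
    decision = accept_decision if p >= p_threshold else reject_decision
    return DiagnosticResult(test_name, f_stat, (df_extra, df_full), p, decision, n_excluded)


def test_parallel_vs_intersecting(
    data: VelocityDataset, varying: str = "B", p_threshold: float = 0.05
) -> DiagnosticResult:
    """Extra-SS F-test of a common slope (parallel lines) vs free slopes.

    Parallel reciprocal lines are the ping-pong signature; rejection means the
    lines intersect, i.e. a sequential (ternary-complex) mechanism.
    """
    return _extra_ss_test(
        data, varying, "slope", "parallel_vs_intersecting", "parallel", "intersecting", p_threshold
    )


def test_yaxis_intersection(
    data: VelocityDataset, varying: str = "B", p_threshold: float = 0.05
) -> DiagnosticResult:
    """Extra-SS F-test of a common intercept (y-axis intersection) vs free intercepts.

    A shared 1/v-axis intercept is the rapid-equilibrium compulsory-order
    signature; rejection places the intersection off the axis, as the
    random-order law with alpha ≠ 1 requires.
    """
    return _extra_ss_test(
        data, varying, "intercept", "yaxis_intersection", "on_y_axis", "off_y_axis", p_threshold
    )


# ---------------------------------------------------------------------------
# global fitting


def _param_names(mechanism: Mechanism) -> tuple[str, ...]:
    if mechanism is Mechanism.RANDOM_RAPID_EQUILIBRIUM:
        return ("k_cat", "K_A", "K_B", "alpha")
    return ("k_cat", "K_A", "K_B")


def _make_params(theta_nat: np.ndarray, mechanism: Mechanism, enzyme_conc: float) -> KineticParameters:
    if mechanism is Mechanism.RANDOM_RAPID_EQUILIBRIUM:
        k_cat, ka, kb, alpha = theta_nat
    else:
        k_cat, ka, kb = theta_nat
        alpha = 1.0
    return KineticParameters(k_cat=k_cat, K_A=ka, K_B=kb, alpha=alpha, enzyme_conc=enzyme_conc)


def _start_grid(data: VelocityDataset, mechanism: Mechanism, enzyme_conc: float, options: FitOptions):
    vmax_obs = max(float(data.v.max()), 1e-12)
    kcat0 = vmax_obs / enzyme_conc
    ka0 = math.sqrt(float(data.a_levels().min()) * float(data.a_levels().max()))
    kb0 = math.sqrt(float(data.b_levels().min()) * float(data.b_levels().max()))
    starts = []
    for fk in options.kcat_factors:
        for fa in options.k_factors:
            for fb in options.k_factors:
                base = [kcat0 * fk, ka0 * fa, kb0 * fb]
                if mechanism is Mechanism.RANDOM_RAPID_EQUILIBRIUM:
                    for al in options.alpha_starts:
                        starts.append(np.array(base + [al]))
                else:
                    starts.append(np.array(base))
    return starts


def fit_global(
    data: VelocityDataset,
    mechanism: Mechanism,
    enzyme_conc: float | None = None,
    options: FitOptions = FitOptions(),
) -> GlobalFitResult:
    """Global least-squares fit of one rate law in velocity space.

    Parameters are fitted on the log scale (positivity by construction); the
    enzyme concentration is a fixed input, never fitted.  All multi-start
    points are run in deterministic order and the best-RSS convergent solution
    wins, ties broken by the lowest k_cat.  Standard errors are asymptotic,
    from the Jacobian at the solution (delta method back to natural scale).
    Non-convergence is reported in the result, not raised.
    """
    mechanism = Mechanism(mechanism)
    if enzyme_conc is None:
        enzyme_conc = data.enzyme_conc
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    if data.a_levels().size < 2 or data.b_levels().size < 2:
        raise ValueError("mechanism inference needs >= 2 distinct levels of each substrate")
    names = _param_names(mechanism)
    a, b, v_obs = data.a, data.b, data.v
    w = options.weights if options.weights is not None else np.ones_like(v_obs)

    def residuals(theta_log: np.ndarray) -> np.ndarray:
        # clip keeps far-flung line-search points finite without moving any optimum
        params = _make_params(np.exp(np.clip(theta_log, -80.0, 80.0)), mechanism, enzyme_conc)
        return w * (velocity(mechanism, params, a, b) - v_obs)

    best = None
    n_used = 0
    for start in _start_grid(data, mechanism, enzyme_conc, options):
        n_used += 1
        try:
            sol = optimize.least_squares(
                residuals,
                np.log(start),
                method="lm",
                ftol=options.ftol,
                xtol=options.xtol,
                gtol=options.gtol,
                max_nfev=options.max_nfev,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if not sol.success:
            continue
        rss = 2.0 * sol.cost
        kcat_here = math.exp(sol.x[0])
        if (
            best is None
            or rss < best[0] * (1 - 1e-12)
            or (abs(rss - best[0]) <= 1e-12 * max(best[0], 1e-300) and kcat_here < best[1])
        ):
            best = (rss, kcat_here, sol)
    n_obs = v_obs.size
    k = len(names)
    if best is None:
        dummy = _make_params(np.exp(np.log(_start_grid(data, mechanism, enzyme_conc, options)[0])), mechanism, enzyme_conc)
        return GlobalFitResult(
            mechanism=mechanism,
            estimates=dummy,
            standard_errors={n: math.nan for n in names},
            covariance=np.full((k, k), math.nan),
            param_names=names,
            rss=math.inf,
            n_obs=n_obs,
            aicc=math.inf,
            converged=False,
            n_restarts_used=n_used,
        )
    rss, _, sol = best
    theta_nat = np.exp(sol.x)
    params = _make_params(theta_nat, mechanism, enzyme_conc)
    dof = max(n_obs - k, 1)
    s2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov_log = s2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov_log = np.full((k, k), math.nan)
    scale = np.diag(theta_nat)
    cov_nat = scale @ cov_log @ scale
    ses = np.sqrt(np.clip(np.diag(cov_nat), 0.0, None))
    return GlobalFitResult(
        mechanism=mechanism,
        estimates=params,
        standard_errors=dict(zip(names, (float(s) for s in ses))),
        covariance=cov_nat,
        param_names=names,
        rss=float(rss),
        n_obs=n_obs,
        aicc=aicc(float(rss), n_obs, k),
        converged=True,
        n_restarts_used=n_used,
    )


def compare_mechanisms(
    data: VelocityDataset,
    enzyme_conc: float | None = None,
    options: FitOptions = FitOptions(),
    with_diagnostics: bool = True,
) -> ModelComparison:
    """Fit all three candidate mechanisms and select by AICc."""
    results: dict[Mechanism, GlobalFitResult] = {}
    for mech in Mechanism:
        res = fit_global(data, mech, enzyme_conc, options)
        if not res.converged:
            warnings.warn(f"{mech.value} fit did not converge; excluded from comparison", stacklevel=2)
            continue
        results[mech] = res
    if not results:
        raise RuntimeError("no mechanism fit converged")
    best_aicc = min(r.aicc for r in results.values())
    delta = {m: r.aicc - best_aicc for m, r in results.items()}
    selected = min(results, key=lambda m: (results[m].aicc, m.value))
    delta[selected] = 0.0
    diagnostics: tuple[DiagnosticResult, ...] = ()
    if with_diagnostics:
        try:
            diagnostics = (
                test_parallel_vs_intersecting(data, p_threshold=options.p_threshold),
                test_yaxis_intersection(data, p_threshold=options.p_threshold),
            )
        except ValueError:
            diagnostics = ()
    return ModelComparison(results=results, delta_aicc=delta, selected=selected, diagnostics=diagnostics)


def bootstrap_uncertainty(
    data: VelocityDataset,
    mechanism: Mechanism,
    n_boot: int = 500,
    seed: int = 0,
    enzyme_conc: float | None = None,
    options: FitOptions = FitOptions(),
    base_fit: GlobalFitResult | None = None,
    stratify_by_cell: bool = False,
) -> BootstrapResult:
    """Case-resampling bootstrap percentile intervals (2.5/97.5).

    By default all observations are resampled with replacement as one pool.
    ``stratify_by_cell`` resamples within each (A, B) grid cell instead, which
    keeps the design balanced but — with few replicates per cell — shrinks the
    resampling variance by the within-cell factor (n−1)/n and makes the
    intervals anti-conservative; it is therefore off by default.  Refits start
    from the base estimates (one start); failed refits are counted, not
    silently dropped.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; percentile intervals will be unstable", stacklevel=2)
    mechanism = Mechanism(mechanism)
    if enzyme_conc is None:
        enzyme_conc = data.enzyme_conc
    if base_fit is None:
        base_fit = fit_global(data, mechanism, enzyme_conc, options)
    if not base_fit.converged:
        raise RuntimeError("base fit did not converge; bootstrap is undefined")
    names = base_fit.param_names
    est = base_fit.estimates
    theta0 = np.log([getattr(est, n) for n in names])
    a, b, v = data.a, data.b, data.v
    cell_indices = None
    if stratify_by_cell:
        cells: dict = {}
        for i in range(len(v)):
            cells.setdefault((a[i], b[i]), []).append(i)
        cell_indices = [np.array(ix) for ix in cells.values()]
    rng = np.random.default_rng(seed)
    samples = []
    n_failures = 0
    for _ in range(n_boot):
        if cell_indices is not None:
            take = np.concatenate(
                [ix[rng.integers(0, ix.size, size=ix.size)] for ix in cell_indices]
            )
        else:
            take = rng.integers(0, v.size, size=v.size)
        ab, bb, vb = a[take], b[take], v[take]

        def residuals(theta_log: np.ndarray) -> np.ndarray:
            params = _make_params(np.exp(np.clip(theta_log, -80.0, 80.0)), mechanism, enzyme_conc)
            return velocity(mechanism, params, ab, bb) - vb

        try:
            sol = optimize.least_squares(
                residuals, theta0, method="lm", ftol=options.ftol, xtol=options.xtol, gtol=options.gtol
            )
        except Exception:
            n_failures += 1
            continue
        if not sol.success:
            n_failures += 1
            continue
        samples.append(np.exp(sol.x))
    if not samples:
        raise RuntimeError("all bootstrap refits failed")
    arr = np.array(samples)
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    intervals = {n: (float(lo[j]), float(hi[j])) for j, n in enumerate(names)}
    return BootstrapResult(intervals=intervals, n_boot=n_boot, n_failures=n_failures, seed=seed, samples=arr)


def cooperativity_fold(result: GlobalFitResult) -> CooperativityFold:
    """Affinity enhancement in the ternary complex, 1/alpha.

    An alpha of 0.24 reads as "each substrate is held about fourfold more
    tightly once the other is bound".
    """
    if not result.converged:
        raise ValueError("cooperativity_fold requires a converged fit")
    alpha = result.estimates.alpha
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    fold = 1.0 / alpha
    return CooperativityFold(fold=fold, rounded=round(fold))
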