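"""End-to-end orchestration: plate data → velocities → mechanism → report.

Reports are plain dictionaries with a versioned schema, serializable to JSON
(byte-identical across reruns with the same inputs and seeds) or rendered as
a human-readable markdown summary.  Warnings from every stage are collected
into the report rather than only logged; a stage failure is recorded under
``failures`` with the stage name and the report is returned partial.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

from . import __version__
from .biophysics import double_reference, extract_req, fit_kinetic_1to1, fit_steady_state
from .config import PipelineConfig
from .data import ProgressCurve, Sensorgram, StandardCurveData, VelocityDataset
from .mechanism_inference import (
    FitOptions,
    bootstrap_uncertainty,
    compare_mechanisms,
    cooperativity_fold,
)
from .rate_laws import Mechanism
from .velocity_extraction import LinearRangeOptions, fit_standard_curve, initial_velocity

__all__ = ["run_kinetics_pipeline", "run_spr_pipeline", "write_report", "read_report", "render_markdown"]

SCHEMA_VERSION = "1"

log = logging.getLogger("glycokinetics.pipeline")


def _provenance(config: PipelineConfig) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
    }


def _caught(record: list[str]):
    return warnings.catch_warnings(record=True)


def run_kinetics_pipeline(
    data: VelocityDataset | None = None,
    config: PipelineConfig = PipelineConfig(),
    curves: list[ProgressCurve] | None = None,
    standard_curve: StandardCurveData | None = None,
) -> dict:
    """Extraction (if plate data) → diagnostics → model comparison → bootstrap → report.

    Provide either a ready ``VelocityDataset`` or raw plate data (``curves`` +
    ``standard_curve``).  Deterministic given the config seed.
    """
    report: dict = {"provenance": _provenance(config), "warnings": [], "failures": []}
    collected: list[str] = []

    def fail(stage: str, exc: Exception) -> dict:
        log.error("stage %s failed: %s", stage, exc)
        report["failures"].append({"stage": stage, "error": str(exc)})
        report["warnings"] = collected
        return report

    if data is None:
        if curves is None or standard_curve is None:
            return fail("inputs", ValueError("need a velocity dataset or plate curves + standard curve"))
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                cal = fit_standard_curve(standard_curve)
                opts = LinearRangeOptions(
                    max_conversion=config.max_conversion,
                    min_points=config.min_points,
                    min_r_squared=config.min_r_squared,
                )
                obs = [initial_velocity(c, cal, opts) for c in curves]
            collected += [str(w.message) for w in wlist]
            enzyme = curves[0].enzyme_conc
            data = VelocityDataset(observations=tuple(obs), enzyme_conc=enzyme)
            report["standard_curve"] = {
                "slope_RLU_per_uM": cal.slope,
                "intercept_RLU": cal.intercept,
                "r_squared": cal.r_squared,
            }
        except Exception as exc:
            return fail("velocity_extraction", exc)

    report["velocity_table"] = {
        "n_obs": len(data),
        "a_levels_uM": [float(x) for x in data.a_levels()],
        "b_levels_uM": [float(x) for x in data.b_levels()],
        "enzyme_nM": data.enzyme_conc,
    }

    fit_opts = FitOptions(p_threshold=config.p_threshold)
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            comparison = compare_mechanisms(data, options=fit_opts)
        collected += [str(w.message) for w in wlist]
    except Exception as exc:
        return fail("mechanism_inference", exc)

    report["diagnostics"] = [
        {
            "test": d.test_name,
            "F": d.statistic,
            "dof": list(d.dof),
            "p_value": d.p_value,
            "decision": d.decision,
        }
        for d in comparison.diagnostics
    ]
    report["model_comparison"] = {
        m.value: {
            "aicc": r.aicc,
            "delta_aicc": comparison.delta_aicc[m],
            "rss": r.rss,
            "converged": r.converged,
        }
        for m, r in comparison.results.items()
    }
    selected = comparison.selected
    best = comparison.results[selected]
    est = best.estimates
    report["selected_mechanism"] = selected.value
    report["parameters"] = {
        "k_cat_per_min": est.k_cat,
        "K_A_uM": est.K_A,
        "K_B_uM": est.K_B,
        "alpha": est.alpha,
        "enzyme_nM": est.enzyme_conc,
        "standard_errors": best.standard_errors,
    }
    if selected is Mechanism.RANDOM_RAPID_EQUILIBRIUM:
        fold = cooperativity_fold(best)
        report["cooperativity"] = {"fold": fold.fold, "rounded": fold.rounded}

    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            boot = bootstrap_uncertainty(
                data, selected, n_boot=config.n_boot, seed=config.seed, options=fit_opts, base_fit=best
            )
        collected += [str(w.message) for w in wlist]
        report["bootstrap"] = {
            "n_boot": boot.n_boot,
            "n_failures": boot.n_failures,
            "intervals_95": {k: list(v) for k, v in boot.intervals.items()},
        }
    except Exception as exc:
        return fail("bootstrap", exc)

    report["warnings"] = collected
    return report


def run_spr_pipeline(
    family: list[Sensorgram],
    config: PipelineConfig = PipelineConfig(),
    solvent_calibration: tuple | None = None,
    kinetic_fit: bool = True,
    analyte: str = "",
) -> dict:
    """Referencing → (solvent correction) → Req extraction → affinity fits.

    ``family`` must contain active and reference cycles plus at least one
    zero-concentration blank cycle pair.
    """
    from .biophysics import solvent_correct

    fragment: dict = {"provenance": _provenance(config), "analyte": analyte, "warnings": [], "failures": []}
    actives = {g.cycle_id: g for g in family if g.role == "active" and g.analyte_conc > 0}
    refs = {g.cycle_id: g for g in family if g.role == "reference" and g.analyte_conc > 0}
    blanks_a = [g for g in family if g.role == "active" and g.analyte_conc == 0]
    blanks_r = [g for g in family if g.role == "reference" and g.analyte_conc == 0]
    if not blanks_a:
        fragment["failures"].append({"stage": "double_reference", "error": "no blank cycles in family"})
        return fragment
    if set(actives) != set(refs):
        fragment["failures"].append(
            {"stage": "double_reference", "error": "active/reference cycles do not pair up"}
        )
        return fragment
    corrected = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for cid in actives:
            c = double_reference(
                actives[cid], refs[cid], blanks_a[0], blanks_r[0] if blanks_r else None
            )
            if solvent_calibration is not None:
                c = solvent_correct(c, solvent_calibration)
            corrected.append(c)
        points = [extract_req(c, window=config.req_window) for c in corrected]
        ss = fit_steady_state(points)
    fragment["warnings"] += [str(w.message) for w in wlist]
    fragment["req_points"] = [
        {"conc_uM": p.conc, "req_RU": p.req, "nonequilibrium": p.nonequilibrium} for p in points
    ]
    fragment["steady_state"] = {
        "kd_uM": ss.kd,
        "kd_se_uM": ss.kd_se,
        "rmax_RU": ss.rmax,
        "offset_RU": ss.offset,
        "saturation_at_top": ss.saturation_at_top,
        "warnings": list(ss.warnings),
    }
    if kinetic_fit:
        try:
            kin = fit_kinetic_1to1(corrected)
            fragment["kinetic_1to1"] = {
                "kon_per_M_s": kin.kon,
                "koff_per_s": kin.koff,
                "rmax_RU": kin.rmax,
                "kd_kinetic_uM": kin.kd_kinetic,
                "converged": kin.converged,
                "flags": list(kin.flags),
            }
        except Exception as exc:
            fragment["failures"].append({"stage": "kinetic_fit", "error": str(exc)})
    return fragment


def write_report(report: dict, path, format: str = "json") -> None:
    """Serialize a report; JSON output is canonical (sorted keys, fixed separators)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    elif format == "markdown":
        path.write_text(render_markdown(report), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def render_markdown(report: dict) -> str:
    lines = ["# Kinetics analysis report", ""]
    prov = report.get("provenance", {})
    lines.append(f"Schema v{prov.get('schema_version', '?')}, package v{prov.get('package_version', '?')}, "
                 f"seed {prov.get('seed', '?')}.")
    lines.append("")
    if "selected_mechanism" in report:
        lines.append(f"**Selected mechanism:** {report['selected_mechanism']}")
        p = report["parameters"]
        lines += [
            "",
            "| parameter | value |",
            "|---|---|",
            f"| k_cat | {p['k_cat_per_min']:.4g} min^-1 |",
            f"| K_A | {p['K_A_uM']:.4g} uM |",
            f"| K_B | {p['K_B_uM']:.4g} uM |",
            f"| alpha | {p['alpha']:.4g} |",
        ]
        if "cooperativity" in report:
            c = report["cooperativity"]
            lines.append(f"| 1/alpha | {c['fold']:.3g} (~{c['rounded']}-fold) |")
    if "steady_state" in report:
        ss = report["steady_state"]
        lines += [
            "",
            f"**Steady-state KD:** {ss['kd_uM']:.4g} uM "
            f"(Rmax {ss['rmax_RU']:.4g} RU, saturation at top {ss['saturation_at_top']:.2f})",
        ]
    for d in report.get("diagnostics", []):
        lines.append(f"- {d['test']}: {d['decision']} (F={d['F']:.3g}, p={d['p_value']:.3g})")
    for f in report.get("failures", []):
        lines.append(f"- FAILED at stage {f['stage']}: {f['error']}")
    if report.get("warnings"):
        lines += ["", "Warnings:"] + [f"- {w}" for w in report["warnings"]]
    return "\n".join(lines) + "\n"
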