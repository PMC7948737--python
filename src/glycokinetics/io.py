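"""CSV readers and writers for every tabular schema the pipeline exchanges.

All files are comma-separated UTF-8 with a header row and units embedded in
the column names; simulated fixtures and real instrument exports are
interchangeable because the generators write exactly these schemas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import ProgressCurve, Sensorgram, StandardCurveData, VelocityDataset

__all__ = [
    "SchemaError",
    "read_velocity_csv",
    "write_velocity_csv",
    "read_progress_csv",
    "write_progress_csv",
    "read_standard_curve_csv",
    "write_standard_curve_csv",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
    "read_sec_csv",
    "write_sec_csv",
]

VELOCITY_COLUMNS = ("a_conc_uM", "b_conc_uM", "velocity_nM_min", "replicate")
PROGRESS_COLUMNS = ("well_id", "a0_uM", "b0_uM", "enzyme_nM", "time_min", "signal_RLU")
STANDARD_COLUMNS = ("udp_conc_uM", "signal_RLU", "replicate")
SENSORGRAM_COLUMNS = (
    "cycle_id",
    "role",
    "analyte_conc_uM",
    "time_s",
    "response_RU",
    "inject_start_s",
    "inject_stop_s",
)
SEC_COLUMNS = ("name", "mw_kda", "elution_ml")


class SchemaError(ValueError):
    """A CSV does not match its documented schema."""


def _load(path, required: tuple[str, ...], numeric: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header row, one for 0-based indexing
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise SchemaError(f"{path}: non-numeric value(s) in column {col!r} at line(s) {lines}")
        if converted.isna().any():
            lines = ", ".join(str(i + 2) for i in df.index[converted.isna()][:5])
            raise SchemaError(f"{path}: empty value(s) in column {col!r} at line(s) {lines}")
        df[col] = converted
    return df


def read_velocity_csv(path, enzyme_conc: float) -> VelocityDataset:
    """Read an initial-velocity table (columns: a_conc_uM, b_conc_uM,
    velocity_nM_min, replicate; optional well_id, velocity_se_nM_min)."""
    df = _load(path, VELOCITY_COLUMNS, ("a_conc_uM", "b_conc_uM", "velocity_nM_min"))
    if "well_id" in df.columns:
        ids = df["well_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise SchemaError(f"{path}: duplicate well id(s): {', '.join(dup.unique()[:5])}")
        well_ids = list(ids)
    else:
        well_ids = None
    se = df["velocity_se_nM_min"].to_numpy() if "velocity_se_nM_min" in df.columns else None
    return VelocityDataset.from_arrays(
        a=df["a_conc_uM"].to_numpy(),
        b=df["b_conc_uM"].to_numpy(),
        v=df["velocity_nM_min"].to_numpy(),
        enzyme_conc=enzyme_conc,
        se=se,
        well_ids=well_ids,
    )


def write_velocity_csv(dataset: VelocityDataset, path) -> None:
    df = dataset.to_frame()
    df["replicate"] = [
        o.well_id.rsplit("_r", 1)[-1] if "_r" in o.well_id else i + 1
        for i, o in enumerate(dataset.observations)
    ]
    df.to_csv(path, index=False)


def write_progress_csv(curves: list[ProgressCurve], path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": c.well_id,
                    "a0_uM": c.a0,
                    "b0_uM": c.b0,
                    "enzyme_nM": c.enzyme_conc,
                    "time_min": c.times,
                    "signal_RLU": c.signal,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_progress_csv(path) -> list[ProgressCurve]:
    df = _load(path, PROGRESS_COLUMNS, ("a0_uM", "b0_uM", "enzyme_nM", "time_min", "signal_RLU"))
    curves = []
    for well, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("time_min")
        curves.append(
            ProgressCurve(
                times=sub["time_min"].to_numpy(),
                signal=sub["signal_RLU"].to_numpy(),
                a0=float(sub["a0_uM"].iloc[0]),
                b0=float(sub["b0_uM"].iloc[0]),
                enzyme_conc=float(sub["enzyme_nM"].iloc[0]),
                well_id=str(well),
            )
        )
    return curves


def write_standard_curve_csv(data: StandardCurveData, path) -> None:
    pd.DataFrame(
        {"udp_conc_uM": data.udp_concs, "signal_RLU": data.signals, "replicate": data.replicates}
    ).to_csv(path, index=False)


def read_standard_curve_csv(path) -> StandardCurveData:
    df = _load(path, STANDARD_COLUMNS, ("udp_conc_uM", "signal_RLU"))
    return StandardCurveData(
        udp_concs=df["udp_conc_uM"].to_numpy(),
        signals=df["signal_RLU"].to_numpy(),
        replicates=df["replicate"].to_numpy(),
    )


def write_sensorgram_csv(family: list[Sensorgram], path) -> None:
    frames = []
    for g in family:
        frames.append(
            pd.DataFrame(
                {
                    "cycle_id": g.cycle_id,
                    "role": g.role,
                    "analyte_conc_uM": g.analyte_conc,
                    "time_s": g.times,
                    "response_RU": g.response,
                    "inject_start_s": g.injection_start,
                    "inject_stop_s": g.injection_stop,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgram_csv(path) -> list[Sensorgram]:
    df = _load(
        path,
        SENSORGRAM_COLUMNS,
        ("analyte_conc_uM", "time_s", "response_RU", "inject_start_s", "inject_stop_s"),
    )
    family = []
    for (cid, role), sub in df.groupby(["cycle_id", "role"], sort=False):
        sub = sub.sort_values("time_s")
        family.append(
            Sensorgram(
                times=sub["time_s"].to_numpy(),
                response=sub["response_RU"].to_numpy(),
                analyte_conc=float(sub["analyte_conc_uM"].iloc[0]),
                role=str(role),
                injection_start=float(sub["inject_start_s"].iloc[0]),
                injection_stop=float(sub["inject_stop_s"].iloc[0]),
                cycle_id=str(cid),
            )
        )
    return family


def write_sec_csv(standards: list[tuple[str, float, float]], path) -> None:
    pd.DataFrame(standards, columns=list(SEC_COLUMNS)).to_csv(path, index=False)


def read_sec_csv(path) -> list[tuple[str, float, float]]:
    df = _load(path, SEC_COLUMNS, ("mw_kda", "elution_ml"))
    return [(str(r["name"]), float(r["mw_kda"]), float(r["elution_ml"])) for _, r in df.iterrows()]
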