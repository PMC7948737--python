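"""In-memory containers shared by the simulation, extraction and biophysics modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NoiseSpec",
    "ProgressCurve",
    "StandardCurveData",
    "Sensorgram",
    "VelocityObservation",
    "VelocityDataset",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: multiplicative CV plus optional additive term.

    ``cv`` is the coefficient of variation of a multiplicative Gaussian factor
    (signal-proportional error, the dominant mode in luminescence assays);
    ``additive_sd`` is an absolute Gaussian term in the signal's own units.
    ``seed`` drives an explicit per-call generator; no global state is touched.
    """

    cv: float = 0.0
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.additive_sd < 0:
            raise ValueError("cv and additive_sd must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Perturb ``values``; exact identity when both noise terms are zero."""
        out = np.asarray(values, dtype=float).copy()
        if self.cv > 0:
            out = out * (1.0 + rng.normal(0.0, self.cv, size=out.shape))
        if self.additive_sd > 0:
            out = out + rng.normal(0.0, self.additive_sd, size=out.shape)
        return out


@dataclass(frozen=True)
class ProgressCurve:
    """Raw luminescent progress curve of one assay well.

    ``signal`` is in relative luminescence units (RLU); conversion to product
    concentration goes through a UDP standard curve.
    """

    times: np.ndarray  # minutes, strictly increasing
    signal: np.ndarray  # RLU
    a0: float  # initial donor concentration, μM
    b0: float  # initial acceptor concentration, μM
    enzyme_conc: float  # nM
    well_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 points")
        if s.shape != t.shape or not np.all(np.isfinite(s)):
            raise ValueError("signal must be finite and match times in length")


@dataclass(frozen=True)
class StandardCurveData:
    """UDP standard-curve measurements: known concentrations vs RLU."""

    udp_concs: np.ndarray  # μM
    signals: np.ndarray  # RLU
    replicates: np.ndarray  # replicate ids

    def __post_init__(self) -> None:
        c = np.asarray(self.udp_concs, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        r = np.asarray(self.replicates)
        object.__setattr__(self, "udp_concs", c)
        object.__setattr__(self, "signals", s)
        object.__setattr__(self, "replicates", r)
        if np.unique(c).size < 3 or 0.0 not in c:
            raise ValueError("need >= 3 distinct concentrations including a 0 background")


@dataclass(frozen=True)
class Sensorgram:
    """One SPR cycle trace: response (RU) vs time (s) at one analyte concentration.

    ``role`` distinguishes the ligand-bearing ("active") from the mock
    ("reference") flow cell; blank buffer cycles carry ``analyte_conc = 0``.
    ``ref_excess`` is filled in by double referencing: the reference-cell bulk
    excess (RU) used as the key of the solvent-correction calibration.
    """

    times: np.ndarray
    response: np.ndarray
    analyte_conc: float  # μM
    role: str  # {"active", "reference"}
    injection_start: float  # s
    injection_stop: float  # s
    cycle_id: str = ""
    ref_excess: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "response", r)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if r.shape != t.shape:
            raise ValueError("response must match times in length")
        if self.role not in ("active", "reference"):
            raise ValueError("role must be 'active' or 'reference'")
        if not (self.injection_start < self.injection_stop <= t[-1]):
            raise ValueError("need injection_start < injection_stop <= max(times)")

    def association_mask(self) -> np.ndarray:
        return (self.times >= self.injection_start) & (self.times <= self.injection_stop)

    def replace_response(self, response: np.ndarray, **updates) -> "Sensorgram":
        kwargs = dict(
            times=self.times,
            response=response,
            analyte_conc=self.analyte_conc,
            role=self.role,
            injection_start=self.injection_start,
            injection_stop=self.injection_stop,
            cycle_id=self.cycle_id,
            ref_excess=self.ref_excess,
        )
        kwargs.update(updates)
        return Sensorgram(**kwargs)


@dataclass(frozen=True)
class VelocityObservation:
    """One initial-velocity measurement at a (donor, acceptor) grid point."""

    a_conc: float  # μM
    b_conc: float  # μM
    velocity: float  # nM/min
    velocity_se: float = 0.0
    linear_window: tuple[int, int] | None = None
    well_id: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.a_conc > 0 and self.b_conc > 0):
            raise ValueError("substrate concentrations must be positive")
        if self.velocity_se < 0:
            raise ValueError("velocity_se must be nonnegative")
        if self.linear_window is not None:
            lo, hi = self.linear_window
            if not (0 <= lo <= hi):
                raise ValueError("linear_window indices must be ordered and nonnegative")


@dataclass(frozen=True)
class VelocityDataset:
    """Collection of initial-velocity observations, the global-fit substrate."""

    observations: tuple[VelocityObservation, ...]
    enzyme_conc: float  # nM
    units: dict = field(
        default_factory=lambda: {"conc": "uM", "velocity": "nM/min", "enzyme": "nM"}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.enzyme_conc > 0:
            raise ValueError("enzyme_conc must be positive")
        if len(self.observations) == 0:
            raise ValueError("dataset must contain observations")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def a(self) -> np.ndarray:
        return np.array([o.a_conc for o in self.observations])

    @property
    def b(self) -> np.ndarray:
        return np.array([o.b_conc for o in self.observations])

    @property
    def v(self) -> np.ndarray:
        return np.array([o.velocity for o in self.observations])

    def a_levels(self) -> np.ndarray:
        return np.unique(self.a)

    def b_levels(self) -> np.ndarray:
        return np.unique(self.b)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a_conc_uM": self.a,
                "b_conc_uM": self.b,
                "velocity_nM_min": self.v,
                "velocity_se_nM_min": [o.velocity_se for o in self.observations],
                "well_id": [o.well_id for o in self.observations],
            }
        )

    @staticmethod
    def from_arrays(
        a: Sequence[float],
        b: Sequence[float],
        v: Sequence[float],
        enzyme_conc: float,
        se: Sequence[float] | None = None,
        well_ids: Sequence[str] | None = None,
    ) -> "VelocityDataset":
        n = len(a)
        se = se if se is not None else [0.0] * n
        well_ids = well_ids if well_ids is not None else [""] * n
        obs = [
            VelocityObservation(
                a_conc=float(a[i]),
                b_conc=float(b[i]),
                velocity=float(v[i]),
                velocity_se=float(se[i]),
                well_id=str(well_ids[i]),
            )
            for i in range(n)
        ]
        return VelocityDataset(observations=tuple(obs), enzyme_conc=enzyme_conc)
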