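"""Pipeline configuration: one strict, flat record of every tunable option."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class PipelineConfig:
    """All options of the end-to-end pipelines, with documented ranges.

    Unknown keys are rejected by :meth:`from_dict`, so a typo in a config file
    fails loudly instead of silently falling back to a default.
    """

    # units declarations (informational; the I/O schemas embed them)
    conc_unit: str = "uM"
    time_unit: str = "min"
    velocity_unit: str = "nM/min"

    # linear-range rule
    max_conversion: float = 0.10  # fraction of the limiting substrate
    min_points: int = 4
    min_r_squared: float = 0.99

    # global-fit options
    p_threshold: float = 0.05  # diagnostic F-test level
    fit_ftol: float = 1e-14

    # bootstrap
    n_boot: int = 500
    seed: int = 0

    # SPR
    req_window: float = 0.10  # final fraction of the association phase

    # output
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_conversion <= 1.0):
            raise ValueError("max_conversion must be in (0, 1]")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if not (0.0 < self.min_r_squared <= 1.0):
            raise ValueError("min_r_squared must be in (0, 1]")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0.0 < self.req_window <= 1.0):
            raise ValueError("req_window must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
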