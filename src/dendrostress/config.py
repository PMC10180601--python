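"""Run configuration: one YAML file drives the whole pipeline.

Every analysis parameter surfaces here with its conventional default
(spline cutoff 0.67 of series length with 50% amplitude, 1000 bootstrap
samples, alpha 0.05, heat-sum base 20 degC, hot-day threshold 30 degC,
frost/ice thresholds 0 degC, rain-day threshold 1 mm) instead of being a
hard-coded literal inside a stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    rwl_path: str = "cores.rwl"
    climate_path: str = "climate_daily.csv"
    output_dir: str = "results"
    species: list[str] | None = None          # None = every species in the file
    study_start: int | None = None            # None = inferred from the data
    study_end: int | None = None
    stress_events: list[int] | str = "auto"   # "auto" -> detect_stress_years
    window_widths: list[int] = field(default_factory=lambda: [1, 2])
    spline_cutoff_fraction: float = 0.67
    spline_amplitude: float = 0.5
    min_depth: int = 2
    biweight_c: float = 9.0
    n_boot: int = 1000
    ci: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    latitude: float = 49.93
    spei_scale: int = 3
    spei_calibration: list[int] | None = None
    missing_tolerance: float = 0.05

    def validate(self) -> None:
        if not 0 < self.spline_cutoff_fraction <= 2:
            raise ValueError("spline_cutoff_fraction out of range")
        if not 0 < self.spline_amplitude < 1:
            raise ValueError("spline_amplitude must be in (0, 1)")
        if any(w not in (1, 2) for w in self.window_widths):
            raise ValueError("window widths must be 1 or 2")
        if isinstance(self.stress_events, str) and self.stress_events != "auto":
            raise ValueError("stress_events must be a year list or 'auto'")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
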