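"""Run configuration: tolerances, instrument constants and paths.

Defaults follow the workflow's standard operating values: 10 ppm for targeted
matching, 20 ppm for database annotation, 0.005 Da for catalogue screening,
0.7% for residual-based class screening, a 26.4 ms acquisition window split
into 200 drift bins, and a 0.01 ms zero-pass separation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .peaktable import DEFAULT_ACQUISITION_WINDOW_MS, DEFAULT_BIN_WIDTH_MS


@dataclass
class RunConfig:
    mz_ppm_match: float = 10.0
    mz_ppm_annotate: float = 20.0
    mz_da_screen: float = 0.005
    residual_threshold_pct: float = 0.7
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS
    window_ms: float = DEFAULT_ACQUISITION_WINDOW_MS
    zero_pass_time_ms: float = 0.01
    n_max_passes: int = 10
    top_n_peaks: int = 500
    min_passes: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "mz_ppm_match",
            "mz_ppm_annotate",
            "mz_da_screen",
            "residual_threshold_pct",
            "bin_width_ms",
            "window_ms",
            "zero_pass_time_ms",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_max_passes < 1 or self.top_n_peaks < 1 or self.min_passes < 2:
            raise ValueError("n_max_passes/top_n_peaks must be >= 1 and min_passes >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def override(self, **kwargs) -> "RunConfig":
        """A copy with non-None keyword values replacing config values."""
        data = self.to_dict()
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)
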