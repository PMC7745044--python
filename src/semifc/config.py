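"""Resolved pipeline configuration with validated defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the analysis chain, with the study defaults.

    Band and filter settings follow the validation study (0.01-0.2 Hz band,
    1.0 Hz low-pass, 1.5 x IQR motion threshold, 60/180 bpm heart-rate
    bounds, channels 16/37 excluded from hemispheric contrasts); the HMS
    constants, semi-metric tolerance and FDR level are declared defaults.
    """

    band: tuple[float, float] = (0.01, 0.2)
    lowpass_cutoff: float = 1.0
    iqr_factor: float = 1.5
    signal_choice: str = "hbo"
    k1: float = -0.6
    k2: float = 2.0
    dpf: tuple[float, float] = (6.0, 6.0)
    source_detector_mm: float = 30.0
    semimetric_tol: float = 1e-9
    weight_eps: float = 1e-6
    roi_map_path: str | None = None
    exclusion_channels: tuple[str, ...] = ("ch16", "ch37")
    hr_bounds_bpm: tuple[float, float] = (60.0, 180.0)
    nn_filter_threshold: float = 0.2
    fdr_q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < low < high")
        if self.signal_choice not in ("hbo", "hbr"):
            raise ValueError("signal_choice must be 'hbo' or 'hbr'")
        if not (self.k1 < 0 < self.k2):
            raise ValueError("HMS constants need k1 < 0 < k2")
        if self.iqr_factor <= 0 or self.lowpass_cutoff <= 0:
            raise ValueError("filter parameters must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band", "dpf", "hr_bounds_bpm", "exclusion_channels"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
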