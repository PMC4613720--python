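"""Pipeline configuration: every tunable constant in one place.

Defaults equal the algorithm's reference operating constants; each field name
states the stage it feeds.  Configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml


@dataclass
class PipelineConfig:
    # pre-processing
    lpf_cutoff_hz: float = 100.0
    lpf_order: int = 8
    downsample_factor: int = 10
    # filter bank
    n_filters: int = 15
    f_min_hz: float = 8.9
    f_max_hz: float = 23.0
    # transient high-pass
    hpf_cutoff_hz: float = 40.0
    hpf_order: int = 8
    # segmentation
    gap_ms: float = 100.0
    max_seg_ms: float = 200.0
    thr_init_factor: float = 3.0
    thr_init_head_s: float = 5.0
    edge_s: float = 0.5
    c1: float = 0.9
    c2: float = 0.1
    r1: float = 1.0 / 3.0
    # classification
    d1_init_s: float = 0.32
    d2_init_s: float = 0.87
    k1: float = 0.85
    k2: float = 1.1
    hr_max_bpm: float = 200.0
    hr_var_slope: float = 3.77
    hr_var_intercept: float = 17.0
    margin_mode: str = "literal"
    # heart rate
    window_len_s: float = 60.0
    hop_s: float = 60.0

    def __post_init__(self) -> None:
        if self.margin_mode not in ("literal", "full"):
            raise ValueError("margin_mode must be 'literal' or 'full'")
        if not 0 < self.f_min_hz < self.f_max_hz:
            raise ValueError("require 0 < f_min_hz < f_max_hz")
        if not (self.k1 < 1 < self.k2):
            raise ValueError("margins must satisfy k1 < 1 < k2")
        if not 0 < self.d1_init_s < self.d2_init_s:
            raise ValueError("require 0 < d1_init_s < d2_init_s")
        for name in ("lpf_cutoff_hz", "hpf_cutoff_hz", "gap_ms", "max_seg_ms",
                     "thr_init_factor", "window_len_s", "hop_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
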