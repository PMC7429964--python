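"""Pipeline configuration: every tunable constant, serializable to YAML.

Defaults follow the standard dynamic-imaging protocol: 100 Hz frame rate,
512-frame cubes, 3% low-frequency trim, 50-sample running-std window,
0.1% highlight clipping, hue rescaled to [0, 0.66] (blue = slow, red =
fast) and saturation to [0, 0.8].
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import DFFOCTError

__all__ = [
    "WelchConfig",
    "RealtimeConfig",
    "RegistrationConfig",
    "OverlayConfig",
    "PipelineConfig",
]


@dataclass
class WelchConfig:
    #: samples per segment; None = n_frames/8 rounded to a power of two
    segment_length: int | None = None
    overlap: float = 0.5
    window: str = "hann"


@dataclass
class RealtimeConfig:
    hop: int = 2
    window_length: int = 128
    #: four increasing edges (Hz) of the low/mid/high bands; None = tertiles
    band_edges: tuple[float, float, float, float] | None = None
    normalization: str = "independent"  # or "running"
    forgetting: float = 0.99


@dataclass
class RegistrationConfig:
    lock_extent_um: float = 10.0
    lock_step_um: float = 0.5
    relock_threshold: float = 0.3  # reported range 0.2-0.4
    target_voxel_edge_um: float = 0.22
    ransac_residual_px: float = 1.0
    seed: int = 0


@dataclass
class OverlayConfig:
    alpha: float = 1.0
    normalize_inputs: bool = True


@dataclass
class PipelineConfig:
    frame_rate: float = 100.0
    n_frames: int = 512
    welch: WelchConfig = field(default_factory=WelchConfig)
    trim_fraction: float = 0.03
    value_window: int = 50
    clip_fraction: float = 0.001
    hue_max: float = 0.66
    saturation_max: float = 0.8
    #: hue rescale endpoints (Hz); None = [post-trim f_min, Nyquist], a
    #: fixed mapping so every frequency keeps the same colour across runs
    frequency_range: tuple[float, float] | None = None
    #: saturation rescale endpoints (Hz^2); None = [0, ((f_hi-f_lo)/2)^2]
    bandwidth_range: tuple[float, float] | None = None
    saturation_statistic: str = "variance"  # or "std"
    normalize_reference: str = "global_mean"
    realtime: RealtimeConfig = field(default_factory=RealtimeConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    overlay: OverlayConfig = field(default_factory=OverlayConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("frequency_range", "bandwidth_range"):
            if d[key] is not None:
                d[key] = list(d[key])
        if d["realtime"]["band_edges"] is not None:
            d["realtime"]["band_edges"] = list(d["realtime"]["band_edges"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        nested = {
            "welch": WelchConfig,
            "realtime": RealtimeConfig,
            "registration": RegistrationConfig,
            "overlay": OverlayConfig,
        }
        kwargs: dict[str, Any] = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, val in d.items():
            if key not in valid:
                raise DFFOCTError(f"unknown config key {key!r}")
            if key in nested and isinstance(val, dict):
                val = nested[key](**val)
            elif key in ("frequency_range", "bandwidth_range") and val is not None:
                val = tuple(val)
            kwargs[key] = val
        cfg = cls(**kwargs)
        if cfg.realtime.band_edges is not None:
            cfg.realtime.band_edges = tuple(cfg.realtime.band_edges)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
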