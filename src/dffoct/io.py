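"""Readers and writers: multi-page TIFF cubes with JSON sidecars, RGB
renderings, per-channel float TIFFs, scene files and run logs.

Cubes are stored with the time axis as TIFF pages (16-bit unsigned, one
page per frame) for universal reader support; the frame rate and free-form
acquisition metadata live in a JSON sidecar next to the TIFF. All writers
are deterministic for deterministic inputs: sorted metadata keys, fixed
compression settings, no timestamps.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .config import PipelineConfig
from .cube import InterferogramCube
from .dynimg import DynamicImage
from .errors import CubeFormatError, MissingFrameRateError
from .synthetic import MotilityScene, scene_from_dict

__all__ = [
    "sidecar_path",
    "read_cube",
    "write_cube",
    "read_scene",
    "write_labels",
    "write_rgb",
    "write_dynamic_image",
    "write_run_log",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def read_cube(path: str | Path, frame_rate: float | None = None) -> InterferogramCube:
    """Read a multi-page TIFF cube; frame rate from sidecar JSON or argument.

    An explicit ``frame_rate`` argument wins over the sidecar. Rejects
    single-page files, ragged pages and missing frame-rate information
    with actionable messages.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (ValueError, tifffile.TiffFileError) as exc:
        raise CubeFormatError(f"cannot read {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.dtype == object:
        raise CubeFormatError(f"{path}: pages have inconsistent shapes")
    if frames.ndim == 2:
        raise CubeFormatError(
            f"{path}: single-page file; a cube needs >= 2 time frames"
        )
    if frames.ndim != 3:
        raise CubeFormatError(f"{path}: expected (t, y, x) pages, got ndim={frames.ndim}")
    metadata: dict[str, Any] = {}
    sidecar = sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            metadata = json.load(fh)
    if frame_rate is None:
        frame_rate = metadata.get("frame_rate")
    if frame_rate is None:
        raise MissingFrameRateError(
            f"{path}: no frame rate in sidecar {sidecar.name}; pass frame_rate "
            "(CLI: --fps)"
        )
    return InterferogramCube(
        frames.astype(float), float(frame_rate),
        metadata=metadata.get("metadata", metadata),
    )


def write_cube(cube: InterferogramCube, path: str | Path) -> Path:
    """Write a cube as 16-bit multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    counts = np.clip(np.rint(cube.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, counts.astype(np.uint16), photometric="minisblack")
    sidecar = sidecar_path(path)
    payload = {
        "frame_rate": cube.frame_rate,
        "n_frames": int(cube.n_frames),
        "shape": list(cube.frames.shape),
        "metadata": cube.metadata,
    }
    sidecar.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    return path


def read_scene(path: str | Path) -> MotilityScene:
    """Load a YAML scene description (see examples/scene.yaml schema)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return scene_from_dict(cfg)


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Ground-truth region indices as an 8-bit PNG."""
    path = Path(path)
    iio.imwrite(path, np.asarray(labels, dtype=np.uint8))
    return path


def write_rgb(rgb: np.ndarray, path: str | Path) -> Path:
    """Write a float [0, 1] RGB image as 8-bit PNG (or TIFF by suffix)."""
    path = Path(path)
    data8 = np.clip(np.rint(np.asarray(rgb) * 255), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data8, photometric="rgb")
    else:
        iio.imwrite(path, data8)
    return path


def write_dynamic_image(
    image: DynamicImage,
    path: str | Path,
    *,
    channels: bool = False,
    config: PipelineConfig | None = None,
) -> Path:
    """Write the RGB rendering, a JSON sidecar with the channel bounds and
    resolved config, and optionally 32-bit float TIFFs per channel."""
    path = Path(path)
    write_rgb(image.rgb, path)
    sidecar = sidecar_path(path)
    payload: dict[str, Any] = {
        "channel_bounds": {
            "frequency_range": list(image.channel_bounds.frequency_range),
            "bandwidth_range": list(image.channel_bounds.bandwidth_range),
            "value_clip": image.channel_bounds.value_clip,
        }
    }
    if config is not None:
        payload["config"] = config.to_dict()
    sidecar.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    if channels:
        for name in ("hue", "saturation", "value"):
            tifffile.imwrite(
                path.with_name(f"{path.stem}_{name}.tif"),
                getattr(image, name).astype(np.float32),
            )
    return path


def write_run_log(
    path: str | Path, config: PipelineConfig, **extras: Any
) -> Path:
    """Run log: the fully resolved configuration plus per-run extras."""
    path = Path(path)
    payload = {"config": config.to_dict(), **extras}
    path.write_text(json.dumps(payload, sort_keys=True, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
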