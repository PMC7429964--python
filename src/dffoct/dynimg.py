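"""Compose the quantitative HSV dynamic image and render it to RGB.

Each colour channel encodes one physical property of the per-pixel
fluctuation:

* **hue** — mean frequency, affinely inverted so the low end of the
  retained frequency range maps to 0.66 (blue) and the high end to 0
  (red); green sits in between.
* **saturation** — frequency bandwidth (``S = P.f^2 - (P.f)^2``),
  inverted and rescaled to [0, 0.8]: a narrowband (tone-like) signal is
  vivid, broadband (noise-like) signal is greyish.
* **value** — fluctuation amplitude: the temporal standard deviation in
  sliding 50-sample windows, averaged over window positions, with the top
  0.1% of pixels clipped for display contrast.

Silent pixels (no fluctuation) get value 0 and render black regardless of
hue. The rescale endpoints are fixed by default (not per-image min/max) so
the same frequency is always shown with the same colour across
acquisitions; for z-stacks the value clip threshold is additionally shared
across planes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.color import hsv2rgb

from .config import PipelineConfig
from .cube import InterferogramCube
from .errors import DFFOCTError, DegenerateRangeError, ShapeMismatchError
from .preprocess import NormalizedCube, normalize_frames
from .spectral import (
    bandwidth_S,
    l1_normalize,
    mean_frequency,
    trim_low_frequencies,
    welch_psd,
)

__all__ = [
    "ChannelBounds",
    "DynamicImage",
    "value_channel",
    "clip_threshold",
    "clip_value",
    "hue_channel",
    "saturation_channel",
    "compose",
    "process_cube",
    "process_stack",
]


@dataclass(frozen=True)
class ChannelBounds:
    """The rescale bounds used to map physical quantities to channels."""

    frequency_range: tuple[float, float]  # Hz, hue endpoints
    bandwidth_range: tuple[float, float]  # Hz^2 (or Hz for std statistic)
    value_clip: float  # counts, amplitude mapped to value 1


@dataclass
class DynamicImage:
    """The H/S/V channel triplet plus its RGB rendering."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray
    rgb: np.ndarray
    channel_bounds: ChannelBounds


def value_channel(
    cube: NormalizedCube | InterferogramCube | np.ndarray, window: int = 50
) -> np.ndarray:
    """Average running standard deviation of each pixel trace.

    The standard deviation (population, ddof=0) is taken in every dense
    sliding window of ``window`` samples fully inside the trace, then
    averaged over window positions. Output is a non-negative amplitude
    map in the cube's count units.
    """
    frames = np.asarray(getattr(cube, "frames", cube), dtype=float)
    n = frames.shape[0]
    if window < 2:
        raise DFFOCTError("window must be >= 2")
    if window > n:
        raise DFFOCTError(f"window ({window}) exceeds trace length ({n})")
    # subtracting the temporal mean leaves windowed stds unchanged but
    # kills the catastrophic cancellation of cumsum-of-squares on large
    # backgrounds (constant traces come out exactly zero)
    x = frames - frames.mean(axis=0, keepdims=True)
    pad_shape = (1,) + x.shape[1:]
    c1 = np.concatenate([np.zeros(pad_shape), np.cumsum(x, axis=0)])
    c2 = np.concatenate([np.zeros(pad_shape), np.cumsum(x * x, axis=0)])
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = np.maximum(s2 / window - (s1 / window) ** 2, 0.0)
    return np.sqrt(var).mean(axis=0)


def clip_threshold(values: np.ndarray | Sequence[np.ndarray], clip_fraction: float) -> float:
    """Nearest-rank (1 - clip_fraction) quantile of the pooled pixels.

    With m pixels, exactly ``floor(clip_fraction * m)`` of the largest
    values lie strictly above the returned threshold when values are
    distinct (ties broken by value order, then index).
    """
    if not 0 <= clip_fraction < 1:
        raise DFFOCTError("clip_fraction must be in [0, 1)")
    if isinstance(values, (list, tuple)):
        pooled = np.concatenate([np.asarray(v).ravel() for v in values])
    else:
        pooled = np.asarray(values).ravel()
    k = int(math.floor(clip_fraction * pooled.size))
    desc = np.sort(pooled)[::-1]
    return float(desc[k])


def clip_value(
    amplitude_map: np.ndarray,
    clip_fraction: float = 0.001,
    *,
    threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Saturate the brightest pixels and rescale the map into [0, 1].

    The highest ``clip_fraction`` of pixels are set to the clip threshold
    (the nearest-rank ``1 - clip_fraction`` quantile) and the map is
    divided by it. Pass ``threshold`` to reuse a shared (e.g. whole-stack)
    threshold. An all-zero map is returned unchanged with a warning.
    """
    amplitude_map = np.asarray(amplitude_map, dtype=float)
    if threshold is None:
        threshold = clip_threshold(amplitude_map, clip_fraction)
    if threshold <= 0:
        warnings.warn("all-zero amplitude map: nothing to rescale")
        return amplitude_map.copy(), 0.0
    return np.minimum(amplitude_map, threshold) / threshold, float(threshold)


def _inverted_affine(
    x: np.ndarray, lo: float, hi: float, out_max: float
) -> np.ndarray:
    if not hi > lo:
        raise DegenerateRangeError(f"degenerate rescale range [{lo}, {hi}]")
    x = np.nan_to_num(np.asarray(x, dtype=float), nan=hi)  # silent -> 0
    return out_max * (hi - np.clip(x, lo, hi)) / (hi - lo)


def hue_channel(
    mean_freq_map: np.ndarray,
    frequency_range: tuple[float, float],
    hue_max: float = 0.66,
) -> np.ndarray:
    """Map mean frequency to hue: ``f_lo -> 0.66`` (blue), ``f_hi -> 0`` (red).

    Out-of-range frequencies are clamped; silent pixels (NaN) get hue 0
    (they render black through the value channel anyway).
    """
    f_lo, f_hi = frequency_range
    return _inverted_affine(mean_freq_map, f_lo, f_hi, hue_max)


def saturation_channel(
    bandwidth_map: np.ndarray,
    bandwidth_range: tuple[float, float],
    saturation_max: float = 0.8,
) -> np.ndarray:
    """Map bandwidth to saturation: zero bandwidth -> 0.8 (vivid), maximal -> 0 (grey)."""
    s_lo, s_hi = bandwidth_range
    return _inverted_affine(bandwidth_map, s_lo, s_hi, saturation_max)


def compose(
    hue: np.ndarray,
    saturation: np.ndarray,
    value: np.ndarray,
    channel_bounds: ChannelBounds | None = None,
) -> DynamicImage:
    """Assemble channels and convert HSV -> RGB (H on the [0, 1] circle)."""
    hue, saturation, value = (np.asarray(c, dtype=float) for c in (hue, saturation, value))
    if not (hue.shape == saturation.shape == value.shape):
        raise ShapeMismatchError(
            f"channel shapes differ: {hue.shape}, {saturation.shape}, {value.shape}"
        )
    eps = 1e-9
    if hue.min() < -eps or hue.max() > 1 + eps:
        raise DFFOCTError("hue out of [0, 1]")
    if saturation.min() < -eps or saturation.max() > 1 + eps:
        raise DFFOCTError("saturation out of [0, 1]")
    if value.min() < -eps or value.max() > 1 + eps:
        raise DFFOCTError("value out of [0, 1]")
    hsv = np.stack(
        [np.clip(hue, 0, 1), np.clip(saturation, 0, 1), np.clip(value, 0, 1)],
        axis=-1,
    )
    rgb = hsv2rgb(hsv)
    if channel_bounds is None:
        channel_bounds = ChannelBounds((0.0, 1.0), (0.0, 1.0), 1.0)
    return DynamicImage(hue, saturation, value, rgb, channel_bounds)


def _spectral_maps(
    cube: InterferogramCube, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """normalize -> Welch -> L1 -> trim -> (f_retained, mean freq, S, value)."""
    norm = normalize_frames(cube, reference=config.normalize_reference)
    f, psd = welch_psd(
        norm.frames,
        cube.frame_rate,
        segment_length=config.welch.segment_length,
        overlap_fraction=config.welch.overlap,
        window=config.welch.window,
    )
    spectrum = l1_normalize(psd, f)
    spectrum = trim_low_frequencies(spectrum, config.trim_fraction)
    mf = mean_frequency(spectrum)
    S = bandwidth_S(spectrum)
    if config.saturation_statistic == "std":
        S = np.sqrt(S)
    elif config.saturation_statistic != "variance":
        raise DFFOCTError(
            f"unknown saturation statistic {config.saturation_statistic!r}"
        )
    vmap = value_channel(norm, config.value_window)
    return spectrum.f, mf, S, vmap


def _resolve_ranges(
    f_retained: np.ndarray, config: PipelineConfig
) -> tuple[tuple[float, float], tuple[float, float]]:
    if config.frequency_range is not None:
        f_lo, f_hi = config.frequency_range
    else:
        f_lo, f_hi = float(f_retained[0]), float(f_retained[-1])
    if config.bandwidth_range is not None:
        s_range = config.bandwidth_range
    else:
        s_max = ((f_hi - f_lo) / 2) ** 2  # largest variance attainable
        if config.saturation_statistic == "std":
            s_max = math.sqrt(s_max)
        s_range = (0.0, s_max)
    return (f_lo, f_hi), s_range


def process_cube(
    cube: InterferogramCube,
    config: PipelineConfig | None = None,
    *,
    value_clip: float | None = None,
) -> DynamicImage:
    """Full chain: cube -> normalized -> per-pixel spectra -> HSV -> RGB.

    Deterministic for a fixed cube and configuration. ``value_clip``
    overrides the 0.1% clip threshold (used by :func:`process_stack` to
    share one threshold across planes).
    """
    config = config or PipelineConfig()
    f_ret, mf, S, vmap = _spectral_maps(cube, config)
    freq_range, band_range = _resolve_ranges(f_ret, config)
    value, thr = clip_value(vmap, config.clip_fraction, threshold=value_clip)
    hue = hue_channel(mf, freq_range, config.hue_max)
    sat = saturation_channel(S, band_range, config.saturation_max)
    bounds = ChannelBounds(freq_range, band_range, thr)
    return compose(hue, sat, value, bounds)


def process_stack(
    cubes: Sequence[InterferogramCube],
    config: PipelineConfig | None = None,
) -> list[DynamicImage]:
    """Process a z-stack with shared channel bounds.

    The value clip threshold is computed once on the pooled pixel
    population of all planes (and the hue/saturation rescale ranges are
    the same fixed ranges for every plane), giving a consistent colour
    map throughout the stack.
    """
    if len(cubes) < 1:
        raise DFFOCTError("stack must contain at least one cube")
    shapes = {c.frames.shape for c in cubes}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"inconsistent cube shapes in stack: {shapes}")
    config = config or PipelineConfig()
    per_plane = [_spectral_maps(c, config) for c in cubes]
    freq_range, band_range = _resolve_ranges(per_plane[0][0], config)
    thr = clip_threshold([vmap for *_ , vmap in per_plane], config.clip_fraction)
    images = []
    for _f, mf, S, vmap in per_plane:
        value, _ = clip_value(vmap, config.clip_fraction, threshold=thr if thr > 0 else None)
        hue = hue_channel(mf, freq_range, config.hue_max)
        sat = saturation_channel(S, band_range, config.saturation_max)
        images.append(compose(hue, sat, value, ChannelBounds(freq_range, band_range, thr)))
    return images
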