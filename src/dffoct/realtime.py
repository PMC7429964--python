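"""Fast three-band RGB variant with streaming output every few frames.

Instead of the full Welch/HSV chain, each pixel's windowed DFT magnitude
is integrated over three frequency bands — low into blue, medium into
green, high into red. Sliding the window by a small hop (default 2
frames) emits a new image every ``hop / frame_rate`` seconds: at 100 Hz
and hop 2 that is one image every 20 ms, a 50 Hz display rate.

This variant is deliberately non-quantitative and noisier than the HSV
pipeline — it exists for live feedback, and only band selectivity and
timing are guaranteed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .config import RealtimeConfig
from .cube import InterferogramCube
from .errors import BandEdgeError, DFFOCTError

__all__ = ["BandDefinition", "three_band_rgb", "RealtimeStream", "stream"]


@dataclass(frozen=True)
class BandDefinition:
    """Four increasing frequencies partitioning the axis into three bands.

    Bands are ``[e0, e1)`` (low -> blue), ``[e1, e2)`` (mid -> green) and
    ``[e2, e3]`` (high -> red); ``e3`` must not exceed Nyquist.
    """

    edges: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) != 4 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise BandEdgeError(f"edges must be 4 increasing frequencies, got {edges}")
        object.__setattr__(self, "edges", edges)

    def validate_against(self, nyquist: float) -> None:
        if self.edges[-1] > nyquist * (1 + 1e-12):
            raise BandEdgeError(
                f"band edge {self.edges[-1]} Hz exceeds Nyquist {nyquist} Hz"
            )

    @classmethod
    def tertiles(cls, frame_rate: float, window_length: int) -> "BandDefinition":
        """Default bands: equal thirds of the post-DC frequency axis."""
        df = frame_rate / window_length
        nyq = frame_rate / 2.0
        span = nyq - df
        return cls((df, df + span / 3, df + 2 * span / 3, nyq))


def three_band_rgb(
    frames: np.ndarray,
    frame_rate: float,
    bands: BandDefinition | None = None,
    *,
    normalize: bool = True,
) -> np.ndarray:
    """Integrate per-pixel DFT magnitudes into a (y, x, 3) RGB image.

    The per-pixel temporal mean (DC) is removed first; magnitudes are
    summed within each band and, when ``normalize`` is on, each channel is
    independently rescaled to [0, 1] by its own maximum.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 8:
        raise DFFOCTError("need a (t, y, x) window of at least 8 frames")
    n = frames.shape[0]
    if bands is None:
        bands = BandDefinition.tertiles(frame_rate, n)
    bands.validate_against(frame_rate / 2.0)
    x = frames - frames.mean(axis=0, keepdims=True)
    mag = np.abs(np.fft.rfft(x, axis=0))
    f = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    e0, e1, e2, e3 = bands.edges
    tol = 1e-12 * frame_rate
    low = mag[(f >= e0 - tol) & (f < e1 - tol)].sum(axis=0)
    mid = mag[(f >= e1 - tol) & (f < e2 - tol)].sum(axis=0)
    high = mag[(f >= e2 - tol) & (f <= e3 + tol)].sum(axis=0)
    rgb = np.stack([high, mid, low], axis=-1)  # R, G, B
    if normalize:
        for c in range(3):
            peak = rgb[..., c].max()
            if peak > 0:
                rgb[..., c] /= peak
    return rgb


class RealtimeStream:
    """Sliding-window sequence of three-band RGB images over a cube.

    Iterating yields ``(start_frame, rgb)`` pairs, one per ``hop`` frames;
    ``interval`` is the emitted inter-image interval in seconds
    (``hop / frame_rate``) and ``output_rate`` its inverse in Hz.
    """

    def __init__(
        self,
        cube: InterferogramCube,
        window_length: int = 128,
        hop: int = 2,
        bands: BandDefinition | None = None,
        normalization: str = "independent",
        forgetting: float = 0.99,
    ) -> None:
        if hop < 1:
            raise DFFOCTError("hop must be >= 1")
        if window_length < 8:
            raise DFFOCTError("window_length must be >= 8")
        if normalization not in ("independent", "running"):
            raise DFFOCTError(f"unknown normalization {normalization!r}")
        self.cube = cube
        self.window_length = window_length
        self.hop = hop
        self.bands = bands or BandDefinition.tertiles(cube.frame_rate, window_length)
        self.bands.validate_against(cube.frame_rate / 2.0)
        self.normalization = normalization
        self.forgetting = forgetting
        if cube.n_frames < window_length:
            warnings.warn(
                f"cube has {cube.n_frames} frames < window {window_length}: no output"
            )

    @property
    def interval(self) -> float:
        """Seconds between emitted images: hop / frame_rate."""
        return self.hop / self.cube.frame_rate

    @property
    def output_rate(self) -> float:
        """Emitted images per second, in Hz."""
        return self.cube.frame_rate / self.hop

    def __len__(self) -> int:
        n = self.cube.n_frames
        if n < self.window_length:
            return 0
        return (n - self.window_length) // self.hop + 1

    def __iter__(self) -> Iterator[tuple[int, np.ndarray]]:
        running_max = np.zeros(3)
        decay = self.forgetting**self.hop
        for i in range(len(self)):
            start = i * self.hop
            window = self.cube.frames[start : start + self.window_length]
            if self.normalization == "independent":
                yield start, three_band_rgb(window, self.cube.frame_rate, self.bands)
                continue
            raw = three_band_rgb(
                window, self.cube.frame_rate, self.bands, normalize=False
            )
            peaks = raw.reshape(-1, 3).max(axis=0)
            running_max = np.maximum(peaks, running_max * decay)
            scale = np.where(running_max > 0, running_max, 1.0)
            yield start, np.clip(raw / scale, 0.0, 1.0)


def stream(
    cube: InterferogramCube,
    window_length: int = 128,
    hop: int = 2,
    bands: BandDefinition | None = None,
    *,
    config: RealtimeConfig | None = None,
) -> RealtimeStream:
    """Build a :class:`RealtimeStream`; ``config`` overrides the defaults."""
    if config is not None:
        window_length = config.window_length
        hop = config.hop
        if config.band_edges is not None:
            bands = BandDefinition(tuple(config.band_edges))
        return RealtimeStream(
            cube, window_length, hop, bands, config.normalization, config.forgetting
        )
    return RealtimeStream(cube, window_length, hop, bands)
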