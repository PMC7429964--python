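"""The raw interferogram cube: a (t, y, x) stack of camera frames.

A dynamic acquisition records many direct interferogram frames (typically
512) at a fixed frame rate (typically 100 Hz) without modulating the
reference arm; every pixel's time trace is then analysed independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DFFOCTError

__all__ = ["InterferogramCube"]


@dataclass
class InterferogramCube:
    """An (n_frames, height, width) stack of non-negative camera counts.

    Parameters
    ----------
    frames
        Array of shape ``(t, y, x)``; intensities in camera counts, all
        non-negative. The first axis is time at a constant frame interval.
    frame_rate
        Camera frame rate in Hz (must be positive).
    metadata
        Free-form acquisition descriptors carried through to output
        sidecars.
    """

    frames: np.ndarray
    frame_rate: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DFFOCTError(
                f"cube must be (t, y, x); got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise DFFOCTError("cube needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise DFFOCTError("cube contains non-finite intensities")
        if self.frames.min() < 0:
            raise DFFOCTError("cube intensities must be non-negative")
        if not self.frame_rate > 0:
            raise DFFOCTError(f"frame_rate must be > 0, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return 1.0 / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Acquisition times of the frames in seconds."""
        return np.arange(self.n_frames) / self.frame_rate
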