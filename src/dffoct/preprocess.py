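"""Frame normalization: divide out camera frame-to-frame exposure drift.

The camera exposure fluctuates slightly from frame to frame; since the
perturbation is multiplicative and global, scaling every frame so its
spatial mean matches a common reference removes it exactly. Applied before
any spectral analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import InterferogramCube
from .errors import DFFOCTError, ZeroMeanFrameError

__all__ = ["NormalizedCube", "normalize_frames"]


@dataclass
class NormalizedCube:
    """An exposure-corrected cube; all frame spatial means are equal."""

    frames: np.ndarray
    frame_rate: float
    normalization_factors: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def normalize_frames(
    cube: InterferogramCube | NormalizedCube,
    *,
    reference: str = "global_mean",
) -> NormalizedCube:
    """Scale each frame so its spatial mean equals a common reference.

    Parameters
    ----------
    cube
        Input cube (raw or already normalized; the operation is
        idempotent).
    reference
        ``"global_mean"`` (default) targets the mean over all frames, so
        the cube's overall mean is preserved; ``"first_frame"`` targets the
        first frame's mean instead.

    Returns
    -------
    NormalizedCube
        With the per-frame scale factors that were applied recorded in
        ``normalization_factors``.
    """
    frames = np.asarray(cube.frames, dtype=float)
    if frames.shape[0] < 2:
        raise DFFOCTError("need at least 2 frames to normalize")
    means = frames.mean(axis=(1, 2))
    tiny = np.finfo(float).tiny
    bad = np.nonzero(np.abs(means) <= tiny)[0]
    if bad.size:
        raise ZeroMeanFrameError(
            f"frame {bad[0]} has zero spatial mean; cannot normalize"
        )
    if reference == "global_mean":
        target = means.mean()
    elif reference == "first_frame":
        target = means[0]
    else:
        raise DFFOCTError(f"unknown normalization reference {reference!r}")
    factors = target / means
    return NormalizedCube(
        frames=frames * factors[:, None, None],
        frame_rate=cube.frame_rate,
        normalization_factors=factors,
    )
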