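"""Fluorescence overlay: calibrate the camera-to-camera projective mapping
and build grey-plus-red composites.

The dynamic-imaging and fluorescence cameras differ in sensor size and
resolution, so a projective transformation (homography) calibrated on a
deformation target maps one plane onto the other. The overlay inserts the
dynamic amplitude (value channel) into all three RGB channels and adds
the registered fluorescence only to red: the dynamic image appears in
greyscale with fluorescence superimposed in red.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .errors import DegenerateCorrespondencesError, DFFOCTError, ShapeMismatchError
from .registration import PlanarTransform

__all__ = ["Correspondences", "fit_projective", "build_overlay"]


@dataclass
class Correspondences:
    """Paired pixel coordinates, (x, y), from the two cameras."""

    points_a: np.ndarray
    points_b: np.ndarray

    def __post_init__(self) -> None:
        self.points_a = np.asarray(self.points_a, dtype=float)
        self.points_b = np.asarray(self.points_b, dtype=float)
        if self.points_a.shape != self.points_b.shape:
            raise DegenerateCorrespondencesError("point counts differ")
        if self.points_a.ndim != 2 or self.points_a.shape[1] != 2:
            raise DegenerateCorrespondencesError("points must be (N, 2)")
        if len(self.points_a) < 4:
            raise DegenerateCorrespondencesError(
                f"homography needs >= 4 pairs, got {len(self.points_a)}"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Correspondences":
        """Read a CSV with header columns x_a,y_a,x_b,y_b."""
        data = np.genfromtxt(path, delimiter=",", names=True)
        pts_a = np.column_stack([data["x_a"], data["y_a"]])
        pts_b = np.column_stack([data["x_b"], data["y_b"]])
        return cls(pts_a, pts_b)

    def to_csv(self, path: str | Path) -> None:
        rows = np.column_stack([self.points_a, self.points_b])
        np.savetxt(path, rows, delimiter=",", header="x_a,y_a,x_b,y_b", comments="")


def fit_projective(
    correspondences: Correspondences,
) -> tuple[PlanarTransform, float]:
    """Least-squares homography (normalized DLT) from point pairs.

    Returns the fitted projective transform (mapping a-coordinates onto
    b-coordinates, matrix normalized to bottom-right entry 1) and the
    reprojection RMS in pixels.
    """
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(
            correspondences.points_a, correspondences.points_b
        )
        ok = bool(tform)
    else:  # older scikit-image
        tform = ProjectiveTransform()
        ok = tform.estimate(correspondences.points_a, correspondences.points_b)
    H = tform.params if ok else np.full((3, 3), np.nan)
    if not ok or not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12:
        raise DegenerateCorrespondencesError(
            "degenerate point configuration: homography is not determined"
        )
    transform = PlanarTransform("projective", H)
    projected = transform.apply(correspondences.points_a)
    residuals = projected - correspondences.points_b
    rms = float(np.sqrt((residuals**2).sum(axis=1).mean()))
    return transform, rms


def _min_max(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    span = image.max() - image.min()
    if span > 0:
        return (image - image.min()) / span
    return np.zeros_like(image)


def build_overlay(
    value: np.ndarray,
    fluorescence: np.ndarray,
    transform: PlanarTransform,
    *,
    alpha: float = 1.0,
    normalize: bool = True,
) -> np.ndarray:
    """Compose the grey-plus-red overlay on the dynamic image's grid.

    ``transform`` maps value-channel (dynamic image) coordinates onto
    fluorescence coordinates; the fluorescence image is resampled
    (bilinear) into the dynamic frame through it. Output channels:
    ``R = clip(value + alpha * fluorescence_registered)``, ``G = B =
    value``, all in [0, 1].
    """
    value = np.asarray(value, dtype=float)
    fluorescence = np.asarray(fluorescence, dtype=float)
    if value.ndim != 2 or fluorescence.ndim != 2:
        raise ShapeMismatchError("value and fluorescence must be 2-D images")
    if abs(np.linalg.det(transform.matrix)) < 1e-12:
        raise DFFOCTError("overlay transform is not invertible")
    if normalize:
        value = _min_max(value)
        fluorescence = _min_max(fluorescence)
    elif value.min() < 0 or value.max() > 1:
        raise DFFOCTError("value channel must be within [0, 1]")
    # warp needs the output->input map; output is the dynamic grid and
    # input the fluorescence grid, which is exactly `transform`
    fluo_registered = warp(
        fluorescence,
        ProjectiveTransform(matrix=transform.matrix),
        output_shape=value.shape,
        order=1,
        preserve_range=True,
    )
    rgb = np.empty(value.shape + (3,))
    rgb[..., 0] = np.clip(value + alpha * fluo_registered, 0.0, 1.0)
    rgb[..., 1] = value
    rgb[..., 2] = value
    return rgb
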