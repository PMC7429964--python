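"""Named exceptions raised across the pipeline.

Every rejection path in the public API raises one of these (all
``ValueError`` subclasses) so callers can distinguish bad inputs from
programming errors.
"""


class DFFOCTError(ValueError):
    """Base class for all pipeline errors."""


class InvalidModelError(DFFOCTError):
    """Unknown or inconsistent fluctuation-model parameters."""


class NoStationarySpectrumError(DFFOCTError):
    """The model has no stationary closed-form power spectrum."""


class OverlappingMasksError(DFFOCTError):
    """Scene region masks overlap."""


class ZeroMeanFrameError(DFFOCTError):
    """A frame with (near) zero spatial mean cannot be normalized."""


class TraceTooShortError(DFFOCTError):
    """Time trace shorter than one analysis segment/window."""


class DegenerateRangeError(DFFOCTError):
    """A rescale range with zero or negative width."""


class ShapeMismatchError(DFFOCTError):
    """Arrays that must share a shape do not."""


class BandEdgeError(DFFOCTError):
    """Frequency-band edges not increasing or beyond Nyquist."""


class ZeroVarianceImageError(DFFOCTError):
    """Constant image: normalized cross-correlation undefined."""


class InsufficientMatchesError(DFFOCTError):
    """Too few feature matches for a transform fit."""


class DegenerateCorrespondencesError(DFFOCTError):
    """Point correspondences insufficient or degenerate for a homography."""


class PatchTooLargeError(DFFOCTError):
    """Denoising patch exceeds the image extent."""


class CubeFormatError(DFFOCTError):
    """Unreadable or inconsistent interferogram cube file."""


class MissingFrameRateError(DFFOCTError):
    """No frame rate available from sidecar metadata or arguments."""
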