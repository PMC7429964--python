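"""Per-pixel power spectrum estimation and its scalar summaries.

Each pixel's trace is reduced to a Welch power spectral density, treated —
after L1 normalization — as a probability distribution over temporal
frequency. Two moments of that distribution drive the colour channels:

* mean frequency  ``P . f``            (hue: slow = blue, fast = red)
* bandwidth       ``S = P.f^2 - (P.f)^2``   (saturation: broad = grey)

The DC bin is always excluded (per-segment mean detrending plus explicit
removal): the static backscattering level is the ordinary FFOCT signal,
not the dynamic one. The lowest 3% of the remaining frequency bins are
trimmed before the moments are taken, removing a low-frequency
instrumental instability; the retained distribution is renormalized.

All operations accept either a single 1-D trace/spectrum or frequency-first
arrays ``(n_bins, ...)`` covering a whole field of view at once.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .errors import DFFOCTError, TraceTooShortError

__all__ = [
    "FrequencySpectrum",
    "SpectralSummary",
    "default_segment_length",
    "welch_psd",
    "l1_normalize",
    "trim_low_frequencies",
    "mean_frequency",
    "bandwidth_S",
    "summarize",
]

#: default fraction of lowest-frequency bins excluded before the moments
DEFAULT_TRIM_FRACTION = 0.03

#: cap on the automatic Welch segment length — beyond ~256 samples the
#: extra frequency resolution buys little while the periodogram variance
#: (fewer averaged segments) grows
_MAX_AUTO_SEGMENT = 256


def default_segment_length(n_frames: int) -> int:
    """n/8 rounded down to a power of two, clipped to [8, 256].

    512-frame acquisitions get 64-sample segments.
    """
    if n_frames < 8:
        raise TraceTooShortError("need at least 8 samples for a spectrum")
    seg = 2 ** int(math.floor(math.log2(max(n_frames // 8, 8))))
    return int(min(max(seg, 8), _MAX_AUTO_SEGMENT, n_frames))


def welch_psd(
    trace: np.ndarray,
    frame_rate: float,
    segment_length: int | None = None,
    overlap_fraction: float = 0.5,
    window: str = "hann",
    *,
    detrend: str = "constant",
    axis: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch averaged-periodogram PSD estimate.

    Returns ``(f, psd)`` with ``f`` from DC to Nyquist spaced
    ``frame_rate / segment_length`` and ``psd`` in density scaling
    (counts^2/Hz), so the integral of the PSD equals the variance of the
    detrended trace (exactly for a single untapered segment, within a few
    percent for the default Hann/50% overlap averaging).
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[axis]
    if segment_length is None:
        segment_length = default_segment_length(n)
    if segment_length < 8:
        raise DFFOCTError("segment_length must be >= 8")
    if n < segment_length:
        raise TraceTooShortError(
            f"trace length {n} shorter than one segment ({segment_length})"
        )
    if not 0 <= overlap_fraction < 1:
        raise DFFOCTError("overlap_fraction must be in [0, 1)")
    noverlap = int(segment_length * overlap_fraction)
    f, psd = _signal.welch(
        trace,
        fs=frame_rate,
        window=window,
        nperseg=segment_length,
        noverlap=noverlap,
        detrend=detrend,
        scaling="density",
        axis=axis,
    )
    if axis != 0:
        psd = np.moveaxis(psd, axis, 0)
    return f, psd


@dataclass
class FrequencySpectrum:
    """An L1-normalized PSD: a probability distribution over frequency.

    ``P`` has the frequency axis first and sums to 1 over it (except at
    silent pixels, where it is all-zero and ``silent`` is set);
    ``total_power`` keeps the pre-normalization fluctuation power
    (counts^2) so amplitude information is not lost.
    """

    P: np.ndarray
    f: np.ndarray
    total_power: np.ndarray
    trim_fraction: float = 0.0
    silent: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.P.shape[0] != self.f.shape[0]:
            raise DFFOCTError("P must be (n_bins, ...) matching f")
        if np.any(np.diff(self.f) <= 0):
            raise DFFOCTError("frequency grid must be strictly increasing")
        if self.silent is None:
            self.silent = np.zeros(self.P.shape[1:], dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.f.shape[0]


def l1_normalize(
    psd: np.ndarray,
    f: np.ndarray,
    *,
    drop_dc: bool = True,
) -> FrequencySpectrum:
    """Normalize a raw PSD to unit sum, as if it were a distribution.

    ``total_power`` is the integral of the raw PSD (trapezoid-free sum
    times the bin width). All-zero pixels (perfectly constant traces) are
    flagged ``silent`` instead of dividing by zero; downstream channels
    render them black.
    """
    psd = np.asarray(psd, dtype=float)
    f = np.asarray(f, dtype=float)
    if psd.shape[0] != f.shape[0]:
        raise DFFOCTError("psd and f disagree on the number of bins")
    if (psd < 0).any():
        raise DFFOCTError("raw PSD must be non-negative")
    if drop_dc and f[0] == 0.0:
        psd, f = psd[1:], f[1:]
    df = f[1] - f[0] if f.size > 1 else 1.0
    totals = psd.sum(axis=0)
    silent = totals == 0
    denom = np.where(silent, 1.0, totals)
    P = psd / denom
    P = np.where(silent, 0.0, P) if P.ndim == 1 else P * ~silent
    return FrequencySpectrum(
        P=P, f=f, total_power=totals * df, silent=np.asarray(silent)
    )


def trim_low_frequencies(
    spectrum: FrequencySpectrum, fraction: float = DEFAULT_TRIM_FRACTION
) -> FrequencySpectrum:
    """Exclude the lowest ``ceil(fraction * n_bins)`` frequency bins.

    Removes the slightly unstable lowest frequencies (sensor/mechanical
    instability) that would otherwise dominate the perceived colour; the
    retained distribution is renormalized to unit sum. Pixels whose whole
    retained power is zero become silent.
    """
    if not 0 <= fraction < 1:
        raise DFFOCTError("trim fraction must be in [0, 1)")
    n_remove = math.ceil(fraction * spectrum.n_bins)
    if n_remove == 0:
        return replace(spectrum, trim_fraction=fraction)
    P = spectrum.P[n_remove:]
    f = spectrum.f[n_remove:]
    totals = P.sum(axis=0)
    newly_silent = totals == 0
    denom = np.where(newly_silent, 1.0, totals)
    P = P / denom
    if P.ndim > 1:
        P = P * ~newly_silent
    elif newly_silent:
        P = np.zeros_like(P)
    return FrequencySpectrum(
        P=P,
        f=f,
        total_power=spectrum.total_power,
        trim_fraction=fraction,
        silent=np.asarray(spectrum.silent | newly_silent),
    )


def mean_frequency(spectrum: FrequencySpectrum) -> np.ndarray | float:
    """First moment ``P . f`` in Hz.

    Silent pixels propagate as NaN (flagged); downstream channels render
    them black through the zero value channel.
    """
    mf = np.einsum("i...,i->...", spectrum.P, spectrum.f)
    return np.where(spectrum.silent, np.nan, mf)[()]


def bandwidth_S(spectrum: FrequencySpectrum) -> np.ndarray | float:
    """Frequency bandwidth ``S = P.f^2 - (P.f)^2`` in Hz^2.

    The variance of frequency under the normalized PSD; zero for a pure
    tone, maximal for power split between the grid extremes. NaN at
    silent pixels.
    """
    m1 = np.einsum("i...,i->...", spectrum.P, spectrum.f)
    m2 = np.einsum("i...,i->...", spectrum.P, spectrum.f**2)
    S = np.maximum(m2 - m1**2, 0.0)
    return np.where(spectrum.silent, np.nan, S)[()]


@dataclass(frozen=True)
class SpectralSummary:
    """The per-pixel scalars that feed the three colour channels."""

    mean_frequency: np.ndarray | float
    bandwidth_S: np.ndarray | float
    total_power: np.ndarray | float


def summarize(spectrum: FrequencySpectrum) -> SpectralSummary:
    return SpectralSummary(
        mean_frequency=mean_frequency(spectrum),
        bandwidth_S=bandwidth_S(spectrum),
        total_power=spectrum.total_power,
    )
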