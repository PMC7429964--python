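"""Forward simulation of interferogram cubes with known per-region motility.

The dynamic contrast in full-field OCT arises from temporal fluctuations of
the backscattered field interfering with the reference arm. The simulator
models each pixel as a two-beam interference signal

    I(t) = B + A * cos(phi(t)) + noise,

where ``B`` is the static (incoherent plus mean interferometric) background
in camera counts, ``A`` the interference amplitude in counts, and ``phi``
a stochastic phase driven by sub-resolution scatterer motion. Moving the
scatterers by a fraction of the wavelength modulates ``phi`` and hence the
counts; the phase dynamics select the fluctuation spectrum:

``static``
    frozen phase — no fluctuation at all (the null pixel).
``brownian_phase``
    Wiener phase, increment variance ``2 * rate * dt`` — free diffusion of
    scatterers; not stationary in phase, intensity decorrelates over
    ``~1/rate``.
``relaxation_phase``
    Ornstein-Uhlenbeck phase about a working point, correlation time
    ``1/rate`` and stationary standard deviation ``phase_std`` —
    confined/tethered motion; in the small-modulation limit its intensity
    spectrum is a Lorentzian with corner frequency ``rate / (2*pi)``.
``white_intensity``
    i.i.d. additive intensity fluctuations of standard deviation
    ``amplitude`` — a spectrally flat null model (e.g. residual camera
    noise).

A :class:`MotilityScene` tiles the field of view with disjoint region
masks, each carrying one model, plus a per-frame multiplicative exposure
drift (what the preprocessing stage divides out) and optional shot noise
(Gaussian, variance equal to the mean counts: the high-count limit of a
camera run close to saturation). Every pixel draws from its own random
substream keyed by (model seed, flat pixel index), so the region layout
never changes the per-pixel noise realisations.

The simulator is a statistical signal generator, not an optics model: no
point-spread function, coherence gating or 3-D scattering is simulated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _signal

from .cube import InterferogramCube
from .errors import (
    DFFOCTError,
    InvalidModelError,
    NoStationarySpectrumError,
    OverlappingMasksError,
)

__all__ = [
    "MODEL_KINDS",
    "FluctuationModel",
    "Region",
    "MotilityScene",
    "AnalyticPSD",
    "simulate_trace",
    "simulate_cube",
    "analytic_psd",
    "fold_psd",
    "disk_mask",
    "rect_mask",
    "scene_from_dict",
    "two_region_scene",
]

MODEL_KINDS = ("static", "brownian_phase", "relaxation_phase", "white_intensity")

#: default stationary phase-modulation depth for relaxation models (rad)
DEFAULT_PHASE_STD = 0.5
#: default interferometric working point: quadrature, maximal sensitivity
DEFAULT_WORKING_POINT = math.pi / 2


@dataclass(frozen=True)
class FluctuationModel:
    """Per-region stochastic model of the interferometric fluctuation.

    Parameters
    ----------
    kind
        One of ``static``, ``brownian_phase``, ``relaxation_phase``,
        ``white_intensity``.
    amplitude
        Interference amplitude ``A`` (camera counts for traces simulated
        standalone; scaled by the scene's ``reference_level`` inside a
        cube). For ``white_intensity`` it is the standard deviation of the
        additive fluctuation.
    rate
        Characteristic rate in Hz: diffusion linewidth (``brownian_phase``)
        or inverse correlation time (``relaxation_phase``). Must be 0 for
        ``static``.
    seed
        Root seed of the model's random substreams.
    phase_std
        Stationary phase excursion (rad) of the relaxation model.
    working_point
        Mean interferometric phase (rad); quadrature by default.
    """

    kind: str
    amplitude: float = 1.0
    rate: float = 0.0
    seed: int = 0
    phase_std: float = DEFAULT_PHASE_STD
    working_point: float = DEFAULT_WORKING_POINT

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise InvalidModelError(
                f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}"
            )
        if self.amplitude < 0:
            raise InvalidModelError("amplitude must be >= 0")
        if self.rate < 0:
            raise InvalidModelError("rate must be >= 0")
        if self.kind == "static" and self.rate != 0:
            raise InvalidModelError("static model must have rate = 0")
        if self.phase_std < 0:
            raise InvalidModelError("phase_std must be >= 0")


@dataclass(frozen=True)
class Region:
    """A boolean mask paired with the fluctuation model active inside it."""

    mask: np.ndarray
    model: FluctuationModel


@dataclass
class MotilityScene:
    """Ground-truth description of a simulated field of view.

    Pixels not covered by any region follow a silent ``static`` model with
    zero amplitude (pure background). ``exposure_drift`` is a per-frame
    multiplicative factor sequence (length ``n_frames``) emulating the
    camera's frame-to-frame exposure instability; ``shot_noise`` adds
    Gaussian noise of variance equal to the mean counts of each sample.
    """

    width: int
    height: int
    regions: list[Region] = field(default_factory=list)
    background_level: float = 20000.0
    reference_level: float = 8000.0
    frame_rate: float = 100.0
    n_frames: int = 512
    exposure_drift: np.ndarray | None = None
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise DFFOCTError("frame_rate must be > 0")
        if self.n_frames < 2:
            raise DFFOCTError("n_frames must be >= 2")
        if self.width < 1 or self.height < 1:
            raise DFFOCTError("scene must be at least 1x1 pixels")
        cover = np.zeros((self.height, self.width), dtype=int)
        for i, region in enumerate(self.regions):
            mask = np.asarray(region.mask, dtype=bool)
            if mask.shape != (self.height, self.width):
                raise DFFOCTError(
                    f"region {i} mask shape {mask.shape} != "
                    f"({self.height}, {self.width})"
                )
            cover += mask
        if (cover > 1).any():
            raise OverlappingMasksError("region masks overlap")
        if self.exposure_drift is not None:
            drift = np.asarray(self.exposure_drift, dtype=float)
            if drift.shape != (self.n_frames,):
                raise DFFOCTError(
                    "exposure_drift must have one factor per frame"
                )
            if (drift <= 0).any():
                raise DFFOCTError("exposure_drift factors must be positive")
            self.exposure_drift = drift

    def label_image(self) -> np.ndarray:
        """Region index per pixel: 0 = uncovered, regions numbered from 1."""
        labels = np.zeros((self.height, self.width), dtype=np.int32)
        for i, region in enumerate(self.regions, start=1):
            labels[np.asarray(region.mask, dtype=bool)] = i
        return labels


def _phase_trace(
    model: FluctuationModel, n_frames: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Stochastic phase phi(t) for the phase-driven model kinds."""
    if model.kind == "static":
        return np.full(n_frames, model.working_point)
    if model.kind == "brownian_phase":
        steps = rng.standard_normal(n_frames - 1) * math.sqrt(2.0 * model.rate * dt)
        phi = np.empty(n_frames)
        phi[0] = model.working_point
        phi[1:] = model.working_point + np.cumsum(steps)
        return phi
    if model.kind == "relaxation_phase":
        sigma = model.phase_std
        rho = math.exp(-model.rate * dt)
        eps = rng.standard_normal(n_frames)
        innovations = sigma * math.sqrt(max(1.0 - rho * rho, 0.0)) * eps
        # exact AR(1) discretisation of the OU process, stationary start
        x0 = sigma * eps[0]
        innovations[0] = 0.0
        dphi, _ = _signal.lfilter([1.0], [1.0, -rho], innovations, zi=[rho * x0])
        dphi[0] = x0
        return model.working_point + dphi
    raise InvalidModelError(f"model kind {model.kind!r} has no phase trace")


def simulate_trace(
    model: FluctuationModel,
    n_frames: int,
    frame_rate: float,
    *,
    background: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one pixel's intensity time series ``I(t)``.

    Returns ``background + A*cos(phi(t))`` for the phase-driven kinds and
    ``background + A*eps(t)`` for ``white_intensity``. Reproducible: the
    same model (including seed) always yields the same trace.
    """
    if n_frames < 2:
        raise DFFOCTError("n_frames must be >= 2")
    if not frame_rate > 0:
        raise DFFOCTError("frame_rate must be > 0")
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(model.seed)))
    dt = 1.0 / frame_rate
    if model.kind == "white_intensity":
        return background + model.amplitude * rng.standard_normal(n_frames)
    phi = _phase_trace(model, n_frames, dt, rng)
    return background + model.amplitude * np.cos(phi)


def _pixel_rng(model: FluctuationModel, pixel_id: int, stream: int = 0):
    """Per-pixel substream: keyed by (model seed, flat pixel index)."""
    ss = np.random.SeedSequence(model.seed, spawn_key=(pixel_id, stream))
    return np.random.Generator(np.random.PCG64(ss))


def simulate_cube(
    scene: MotilityScene,
) -> tuple[InterferogramCube, np.ndarray]:
    """Simulate a full cube; returns ``(cube, label_image)``.

    Every pixel's trace follows its region's model; the exposure drift is
    applied uniformly within each frame; optional shot noise (variance =
    mean counts) is added last. Deterministic for a given scene.
    """
    h, w, n = scene.height, scene.width, scene.n_frames
    frames = np.full((n, h, w), float(scene.background_level))

    silent = FluctuationModel("static", amplitude=0.0, seed=0)
    covered = np.zeros((h, w), dtype=bool)
    region_models: list[tuple[np.ndarray, FluctuationModel]] = []
    for region in scene.regions:
        mask = np.asarray(region.mask, dtype=bool)
        region_models.append((mask, region.model))
        covered |= mask
    if not covered.all():
        region_models.append((~covered, silent))

    for mask, model in region_models:
        if model.kind == "static" and model.amplitude == 0.0:
            continue  # background already in place
        ys, xs = np.nonzero(mask)
        amp_counts = model.amplitude * scene.reference_level
        scaled = FluctuationModel(
            model.kind,
            amplitude=amp_counts,
            rate=model.rate,
            seed=model.seed,
            phase_std=model.phase_std,
            working_point=model.working_point,
        )
        for y, x in zip(ys, xs):
            pid = int(y) * w + int(x)
            rng = _pixel_rng(model, pid)
            frames[:, y, x] = simulate_trace(
                scaled, n, scene.frame_rate,
                background=scene.background_level, rng=rng,
            )

    if scene.exposure_drift is not None:
        frames *= np.asarray(scene.exposure_drift)[:, None, None]

    if scene.shot_noise:
        for y in range(h):
            for x in range(w):
                pid = y * w + x
                model = next(m for mk, m in region_models if mk[y, x])
                rng = _pixel_rng(model, pid, stream=1)
                mean_counts = np.maximum(frames[:, y, x], 0.0)
                frames[:, y, x] += np.sqrt(mean_counts) * rng.standard_normal(n)

    frames = np.maximum(frames, 0.0)
    cube = InterferogramCube(
        frames,
        scene.frame_rate,
        metadata={
            "simulated": True,
            "background_level": scene.background_level,
            "reference_level": scene.reference_level,
            "shot_noise": scene.shot_noise,
        },
    )
    return cube, scene.label_image()


@dataclass(frozen=True)
class AnalyticPSD:
    """Closed-form one-sided power spectral density of a model's trace.

    ``curve(f)`` evaluates the continuous density (counts^2/Hz) at any
    non-negative frequencies; ``delta_dc_power`` is any power concentrated
    in a Dirac at f = 0 (the static model puts all of it there).
    ``total_power`` is the fluctuation variance the curve integrates to.
    """

    kind: str
    curve: Callable[[np.ndarray], np.ndarray]
    total_power: float
    delta_dc_power: float = 0.0

    def __call__(self, f: np.ndarray) -> np.ndarray:
        return self.curve(np.asarray(f, dtype=float))


def analytic_psd(model: FluctuationModel, frame_rate: float) -> AnalyticPSD:
    """Expected PSD for kinds with a closed form.

    ``white_intensity`` is flat at ``2 A^2 / frame_rate`` up to Nyquist;
    ``relaxation_phase`` (at the quadrature working point) is an exact sum
    of Lorentzians of half-widths ``(2k+1) * rate / (2*pi)`` obtained from
    the sinh-form autocovariance of cos(OU); the leading term is the
    small-modulation Lorentzian with corner ``rate / (2*pi)``.
    ``brownian_phase`` has no stationary closed form and is rejected.
    """
    if model.kind == "brownian_phase":
        raise NoStationarySpectrumError(
            "brownian_phase has no stationary closed-form spectrum; "
            "use an empirical (simulated) oracle"
        )
    nyquist = frame_rate / 2.0
    if model.kind == "static":
        power = model.amplitude**2 * math.cos(model.working_point) ** 2

        def zero_curve(f: np.ndarray) -> np.ndarray:
            return np.zeros_like(np.asarray(f, dtype=float))

        return AnalyticPSD("static", zero_curve, 0.0, delta_dc_power=power)
    if model.kind == "white_intensity":
        level = 2.0 * model.amplitude**2 / frame_rate

        def flat_curve(f: np.ndarray) -> np.ndarray:
            f = np.asarray(f, dtype=float)
            return np.where(f <= nyquist, level, 0.0)

        return AnalyticPSD(
            "white_intensity", flat_curve, model.amplitude**2
        )
    # relaxation_phase at quadrature: R(tau) = A^2 e^{-s2} sinh(s2 e^{-r|tau|})
    if not math.isclose(model.working_point % math.pi, math.pi / 2, abs_tol=1e-9):
        raise NoStationarySpectrumError(
            "closed form implemented at the quadrature working point only"
        )
    if model.rate == 0:
        raise NoStationarySpectrumError(
            "relaxation_phase with rate = 0 is a frozen phase (no spectrum)"
        )
    s2 = model.phase_std**2
    a2 = model.amplitude**2
    theta = model.rate
    # sinh(s2 x) = sum_k s2^(2k+1) x^(2k+1) / (2k+1)!
    coeffs: list[tuple[float, float]] = []
    k = 0
    while True:
        m = 2 * k + 1
        c = a2 * math.exp(-s2) * s2**m / math.factorial(m)
        coeffs.append((c, m * theta))
        if c < 1e-14 * a2 or k > 40:
            break
        k += 1
    total = a2 * math.exp(-s2) * math.sinh(s2)

    def lorentzian_sum(f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        w2 = (2.0 * math.pi * f) ** 2
        out = np.zeros_like(f)
        for c, g in coeffs:
            out += c * 4.0 * g / (g * g + w2)
        return out

    return AnalyticPSD("relaxation_phase", lorentzian_sum, total)


def fold_psd(
    psd: AnalyticPSD | Callable[[np.ndarray], np.ndarray],
    freqs: np.ndarray,
    frame_rate: float,
    n_folds: int = 6,
) -> np.ndarray:
    """Alias a continuous one-sided PSD onto the sampled frequency grid.

    Sampling at ``frame_rate`` folds power from ``|f + j*frame_rate|``
    (all integers j) back into [0, Nyquist]; a handful of folds suffices
    for spectra with 1/f^2 tails.
    """
    freqs = np.asarray(freqs, dtype=float)
    out = np.zeros_like(freqs)
    for j in range(-n_folds, n_folds + 1):
        out += psd(np.abs(freqs + j * frame_rate))
    return out


# ---------------------------------------------------------------------------
# scene construction helpers

def disk_mask(height: int, width: int, center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disk; ``center`` is (row, col)."""
    yy, xx = np.mgrid[0:height, 0:width]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def rect_mask(
    height: int, width: int, top: int, left: int, h: int, w: int
) -> np.ndarray:
    mask = np.zeros((height, width), dtype=bool)
    mask[top : top + h, left : left + w] = True
    return mask


def _mask_from_spec(shape_spec: dict, height: int, width: int) -> np.ndarray:
    kind = shape_spec.get("type", "rect")
    if kind == "disk":
        return disk_mask(height, width, tuple(shape_spec["center"]), shape_spec["radius"])
    if kind == "rect":
        return rect_mask(
            height, width,
            shape_spec["top"], shape_spec["left"],
            shape_spec["height"], shape_spec["width"],
        )
    if kind == "full":
        return np.ones((height, width), dtype=bool)
    raise DFFOCTError(f"unknown region shape type {kind!r}")


def _drift_from_spec(spec, n_frames: int) -> np.ndarray | None:
    if spec is None:
        return None
    if isinstance(spec, (list, tuple, np.ndarray)):
        return np.asarray(spec, dtype=float)
    kind = spec.get("kind", "none")
    if kind == "none":
        return None
    t = np.arange(n_frames)
    if kind == "sinusoidal":
        amp = float(spec.get("amplitude", 0.02))
        period = float(spec.get("period", 100))
        return 1.0 + amp * np.sin(2 * np.pi * t / period)
    if kind == "linear":
        slope = float(spec.get("slope", 1e-4))
        return 1.0 + slope * t
    raise DFFOCTError(f"unknown exposure drift kind {kind!r}")


def scene_from_dict(cfg: dict) -> MotilityScene:
    """Build a scene from a plain dict (the YAML scene-file schema)."""
    height = int(cfg["height"])
    width = int(cfg["width"])
    n_frames = int(cfg.get("n_frames", 512))
    regions = []
    for rspec in cfg.get("regions", []):
        mask = _mask_from_spec(rspec["shape"], height, width)
        mspec = dict(rspec["model"])
        regions.append(Region(mask=mask, model=FluctuationModel(**mspec)))
    return MotilityScene(
        width=width,
        height=height,
        regions=regions,
        background_level=float(cfg.get("background_level", 20000.0)),
        reference_level=float(cfg.get("reference_level", 8000.0)),
        frame_rate=float(cfg.get("frame_rate", 100.0)),
        n_frames=n_frames,
        exposure_drift=_drift_from_spec(cfg.get("exposure_drift"), n_frames),
        shot_noise=bool(cfg.get("shot_noise", False)),
    )


def two_region_scene(
    *,
    size: int = 32,
    rate_slow: float = 2.0,
    rate_fast: float = 20.0,
    amplitude: float = 0.4,
    frame_rate: float = 100.0,
    n_frames: int = 512,
    seed: int = 0,
    shot_noise: bool = False,
) -> MotilityScene:
    """Convenience scene: left half slow, right half fast relaxation motion."""
    left = rect_mask(size, size, 0, 0, size, size // 2)
    right = rect_mask(size, size, 0, size // 2, size, size - size // 2)
    return MotilityScene(
        width=size,
        height=size,
        regions=[
            Region(left, FluctuationModel("relaxation_phase", amplitude, rate_slow, seed=seed)),
            Region(right, FluctuationModel("relaxation_phase", amplitude, rate_fast, seed=seed + 1)),
        ],
        frame_rate=frame_rate,
        n_frames=n_frames,
        shot_noise=shot_noise,
    )
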