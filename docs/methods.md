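# Methods

## The measurement being modelled

Dynamic full-field OCT records, at a fixed depth, a movie of the
interferogram formed by light backscattered from the sample and light from
the reference arm — typically 512 frames at 100 Hz, with no reference-arm
modulation. Sub-resolution motion of intracellular scatterers modulates
the optical path length and hence, through interference, the counts on
each camera pixel. The pipeline turns each pixel's time trace into three
physical numbers and displays them as HSV colour: brightness is
fluctuation amplitude, hue is fluctuation speed (blue = slow, red = fast),
and saturation is spectral purity (narrowband = vivid, noise-like = grey).

## Processing chain and its constants

1. **Exposure normalization.** Each frame is rescaled so its spatial mean
   equals the cube's global mean (switchable to first-frame reference).
   The camera instability being corrected is multiplicative and global,
   so this inverts it exactly and is idempotent. The statistic is the
   mean, not the median — the perturbation model is a pure gain, where
   the mean is sufficient.
2. **Per-pixel Welch PSD.** Averaged modified periodograms, Hann taper,
   50% overlap, density scaling. The default segment length is n/8
   rounded down to a power of two and capped at 256 samples (64 for a
   512-frame cube). The cap is a variance/resolution trade-off: beyond
   ~0.4 Hz resolution the extra detail is unused by the colour mapping,
   while halving the number of averaged segments visibly roughens the
   spectra. All three parameters are exposed in `WelchConfig`.
3. **DC exclusion.** Traces are mean-detrended per segment and the DC bin
   is dropped: the static backscattering level is the ordinary (static)
   OCT signal, not a dynamic quantity.
4. **L1 normalization** turns each raw PSD into a probability
   distribution over frequency; the pre-normalization fluctuation power
   is kept separately. All-zero spectra (perfectly constant pixels) are
   flagged *silent*, never divided.
5. **Low-frequency trim.** The lowest ceil(3% of bins) are removed and
   the distribution renormalized — the lowest frequencies carry
   sensor/mechanical instability that would otherwise dominate the
   perceived colour. Trimming operates on frequency *bins*, not
   cumulative power, because the artefact is localized at the bottom of
   the grid. Trim happens after L1 normalization (then renormalizes), so
   the order is immaterial to the result.
6. **Moments.** Hue derives from the mean frequency `P·f`; saturation
   from the bandwidth `S = P·f² − (P·f)²` — the variance of frequency
   under `P` (units Hz²). `S` is used as the variance it is; a
   `saturation_statistic="std"` option uses its square root instead,
   since "frequency histogram width" is arguably a standard deviation.
7. **Channels.**
   - *Value*: the standard deviation (population, ddof = 0, a negligible
     ~1% bias at window 50) in dense sliding 50-sample windows fully
     inside the trace, averaged over window positions; then the top 0.1%
     of pixels (nearest-rank quantile, floor of fraction·m pixels) are
     clipped to the threshold and the map divided by it.
   - *Hue*: affine, inverted — the low end of the frequency range maps to
     0.66 (blue in HSV, ≈ 240°) and the high end to 0 (red); out-of-range
     values clamp. The default range is fixed at [first retained
     frequency, Nyquist] rather than per-image min/max, so a given
     frequency is always the same colour across acquisitions and planes;
     per-image autoscale is available via `frequency_range`.
   - *Saturation*: affine, inverted, into [0, 0.8]; the default bandwidth
     range is [0, ((f_hi−f_lo)/2)²], the largest variance attainable on
     the retained grid.
   - HSV → RGB by the standard conversion; silent pixels have value 0 and
     render black regardless of hue.
8. **Stacks.** For z-stacks the value clip threshold is computed once on
   the pooled pixel population (and the fixed hue/saturation ranges are
   shared), giving one consistent colour map through depth.

## Real-time three-band variant

For live display, each pixel's windowed DFT magnitude (DC removed) is
summed over three bands — low→blue, mid→green, high→red — with default
edges at tertiles of the post-DC axis and a default 128-frame window
sliding by 2 frames: one image per 20 ms at 100 Hz (50 Hz output). This
variant is non-quantitative by design; only band selectivity and timing
are guaranteed. Each emitted image normalizes its channels independently
by default, which makes tumbling-window streaming bit-identical to batch
processing; a running-maximum mode with exponential forgetting
(0.99/frame) is available for flicker-free live display.

## Drift correction and registration

- **Plane locking**: axial drift (~5 µm/h thermally, against 1.7 µm axial
  resolution) is corrected by scanning ±10 µm in 0.5 µm steps and picking
  the plane maximizing the zero-mean normalized (Pearson) cross-correlation
  with a stored target; the relock trigger fires when the correlation with
  the current image drops below a threshold (default 0.3; the useful range
  is roughly 0.2–0.4, and healthy peak correlations 0.5–0.8 on real
  tissue). Peak selection is a grid argmax without sub-step refinement —
  the motor moves in the same 0.5 µm steps as the scan.
- **Lateral registration**: SIFT keypoints matched with cross-checked
  descriptor matching, rigid (rotation + translation) fit by RANSAC with a
  fixed seed for determinism; each plane is aligned to the first plane of
  the stack (sequential chaining was considered and rejected as the
  default because error accumulates). Planes with too few matches are
  flagged and passed through with an identity transform rather than
  aborting a whole stack.
- **Depth interpolation**: cubic-spline resampling along z to 220 nm
  isotropic voxels (the lateral pitch of the instrument's sampling);
  cubic interpolation reproduces constants and linear ramps exactly, and
  fewer than 4 planes fall back to linear with a warning.
- **Non-local means** denoising is display-side only and off by default.

## Fluorescence overlay

A projective transform (normalized-DLT homography, ≥ 4 non-collinear point
pairs from a calibration target) maps the dynamic camera's plane onto the
fluorescence camera's. Overlays are built on the dynamic grid: the value
channel fills all three RGB channels and the registered fluorescence is
added (gain α, default 1, inputs min–max normalized) to red only, with
clipping — grey anatomy, red label. Warping is bilinear: overlays are for
display, where sub-pixel smoothness beats interpolation fidelity.

## The simulator

Each pixel is a two-beam interference signal
`I(t) = B + A·cos(φ(t)) + noise` with the phase dynamics selecting the
fluctuation spectrum: frozen phase (static), Wiener phase with increment
variance 2·rate·Δt (free diffusion), or an Ornstein–Uhlenbeck phase with
correlation time 1/rate and stationary excursion `phase_std` (confined
motion; the default working point is quadrature, where sensitivity is
maximal). A flat additive model (`white_intensity`) serves as the
noise-floor null. Scenes add a per-frame multiplicative exposure drift
(what normalization must divide out) and optionally Gaussian shot noise
with variance equal to the mean counts — the high-count limit appropriate
to a camera operated near saturation. Defaults (512 frames, 100 Hz,
background 20 000 counts, interference amplitude a fraction of an
8 000-count reference level) mirror the standard acquisition protocol.

Randomness is reproducible and layout-independent: each pixel draws from
a substream keyed by (model seed, flat pixel index), so editing one
region's mask never changes another pixel's realisation.

For the relaxation model at quadrature the intensity autocovariance has
the closed form `R(τ) = A² e^{−σ²} sinh(σ² e^{−rate·|τ|})`, whose Fourier
transform is a series of Lorentzians of half-widths (2k+1)·rate/(2π); the
leading term is the familiar small-modulation Lorentzian with corner
rate/(2π). `analytic_psd` evaluates this exactly (plus flat and
delta-at-DC forms for the other kinds; Wiener phase has no stationary
spectrum and is rejected by name), and `fold_psd` aliases the continuous
curve onto a sampled grid for comparison with Welch estimates.

### What the simulator does and does not establish

It validates the *signal-processing* chain: spectral estimation against
closed forms, channel mappings against their endpoint conventions,
registration against known transforms. It is not an optics model — no
point-spread function, coherence gating, speckle statistics across
pixels, or 3-D scattering — and the fluctuation statistics of real
organelles are unknown; simulator rates and amplitudes are chosen for
test coverage, not biological fidelity. Passing tests therefore
demonstrate that the pipeline measures what it claims on signals with
known spectra, not that any particular tissue has those spectra.

## Numerical choices

- Running-std windows subtract the per-pixel temporal mean first: the
  windowed standard deviation is shift-invariant, and this removes the
  catastrophic cancellation of cumulative sums on 20 000-count
  backgrounds (constant traces come out exactly zero).
- The 0.1% clip uses the nearest-rank quantile on the pooled population,
  ties broken by value order then index, so the clipped count is exactly
  floor(fraction·m) for distinct values.
- Anti-correlation is floored to 0 in the relock trigger; a zero
  threshold therefore never fires.
- Degenerate inputs are rejected with named errors (`errors.py`):
  zero-mean frames, all-zero spectra (flagged silent, propagated as NaN),
  constant images in correlation, collinear calibration points,
  band edges beyond Nyquist, patches larger than the image.
- Problem sizes in the test-suite and the acceptance script (16–48 px
  fields, 256–512 frames, 2^15-sample traces for spectral oracles) are
  chosen so every check runs in seconds while keeping estimator noise
  well inside the asserted tolerances.

## Known limitations

- The simulator's per-pixel independence means no spatial speckle
  correlation; metrics that pool neighbouring pixels see slightly
  optimistic variance.
- Welch defaults assume roughly stationary traces over the cube; strongly
  non-stationary motility (e.g. a cell dying mid-acquisition) smears the
  spectrum and the colour reflects the average.
- The three-band stream trades quantitativeness for speed, as designed.
- Plane locking reports grid-resolution offsets (0.5 µm); sub-step
  parabolic refinement is deliberately not the default.
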