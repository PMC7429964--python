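import math

import numpy as np
import pytest
from scipy import ndimage

from dffoct import InterferogramCube, PipelineConfig, WelchConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def textured_image(rng):
    """Smooth random texture with plenty of features for matching."""
    img = ndimage.gaussian_filter(rng.standard_normal((128, 128)), 3)
    return (img - img.min()) / (img.max() - img.min())


def make_tone_cube(n_frames=512, frame_rate=100.0, background=1000.0):
    """Cube of on-grid cosine pixels spanning the full frequency range.

    Pixels come in +/- phase pairs so every frame's spatial mean is
    exactly the background (normalization factors are exactly 1). With a
    single full-length boxcar Welch segment each tone is an exact delta
    on the grid, hitting the hue/saturation rescale endpoints.
    """
    t = np.arange(n_frames) / frame_rate
    seg = n_frames
    df = frame_rate / seg
    n_bins = seg // 2  # after the DC bin is dropped
    n_trim = math.ceil(0.03 * n_bins)
    f_lo = (1 + n_trim) * df  # first retained frequency
    f_hi = frame_rate / 2.0
    frames = np.full((n_frames, 4, 4), background)
    tones = [(0, f_lo, 100.0), (1, f_hi, 80.0), (2, (f_lo + f_hi) / 2, 50.0)]
    for row, freq, amp in tones:
        # snap to the exact grid
        freq = round(freq / df) * df
        frames[:, row, 0] = background + amp * np.cos(2 * np.pi * freq * t)
        frames[:, row, 1] = background - amp * np.cos(2 * np.pi * freq * t)
    cube = InterferogramCube(frames, frame_rate)
    config = PipelineConfig(
        welch=WelchConfig(segment_length=seg, overlap=0.0, window="boxcar")
    )
    return cube, config, f_lo, f_hi


@pytest.fixture
def tone_cube():
    return make_tone_cube()
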