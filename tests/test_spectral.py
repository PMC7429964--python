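"""Spectral estimation: Welch oracle, L1 normalization, trim, moments."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dffoct import (
    FluctuationModel,
    MotilityScene,
    Region,
    bandwidth_S,
    l1_normalize,
    mean_frequency,
    process_cube,
    simulate_cube,
    trim_low_frequencies,
    welch_psd,
)
from dffoct.errors import DFFOCTError, TraceTooShortError
from dffoct.spectral import FrequencySpectrum, default_segment_length, summarize


def brute_force_periodogram(trace, frame_rate):
    """Direct DFT-sum periodogram, density scaling — the oracle."""
    x = np.asarray(trace, dtype=float)
    x = x - x.mean()
    n = len(x)
    k = np.arange(n // 2 + 1)
    W = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    X = W @ x
    P = np.abs(X) ** 2 / (frame_rate * n)
    last = -1 if n % 2 == 0 else None
    P[1:last] *= 2  # one-sided: double all but DC (and Nyquist when present)
    return k * frame_rate / n, P


class TestWelch:
    @pytest.mark.parametrize("n", [64, 100, 256])
    def test_single_segment_equals_brute_force_periodogram(self, rng, n):
        """Untapered single-segment Welch == direct DFT sum (non-DC bins)."""
        trace = rng.standard_normal(n) * 3.0 + 50.0
        f_ref, p_ref = brute_force_periodogram(trace, 100.0)
        f, p = welch_psd(trace, 100.0, segment_length=n, overlap_fraction=0.0,
                         window="boxcar")
        np.testing.assert_allclose(f, f_ref, rtol=1e-12)
        rel = np.abs(p[1:] - p_ref[1:]) / p_ref[1:]
        assert rel.max() < 1e-9

    def test_pure_tone_peaks_at_its_bin(self):
        fs, n, f0 = 100.0, 512, 12.5
        t = np.arange(n) / fs
        f, p = welch_psd(np.sin(2 * np.pi * f0 * t), fs, segment_length=128)
        assert f[np.argmax(p)] == pytest.approx(f0)

    def test_constant_trace_has_no_ac_power(self):
        f, p = welch_psd(np.full(256, 7.0), 100.0, segment_length=64)
        assert np.all(p[1:] == 0.0)

    def test_white_noise_spectrum_is_flat(self, rng):
        """CV across non-DC bins < 0.2 at the default averaging, 2^15 samples."""
        f, p = welch_psd(rng.standard_normal(2**15), 100.0)
        p = p[1:]
        assert p.std() / p.mean() < 0.2

    def test_parseval_within_5_percent_for_default_taper(self, rng):
        x = rng.standard_normal(4096)
        f, p = welch_psd(x, 100.0)
        assert np.sum(p) * (f[1] - f[0]) == pytest.approx(x.var(), rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(TraceTooShortError):
            welch_psd(np.ones(32), 100.0, segment_length=64)

    def test_default_segment_length_is_n_over_8_power_of_two(self):
        assert default_segment_length(512) == 64
        assert default_segment_length(1000) == 64
        assert default_segment_length(64) == 8


class TestL1Normalize:
    def test_simple_normalization(self):
        spec = l1_normalize(np.array([2.0, 6.0, 2.0]), np.array([1.0, 2.0, 3.0]),
                            drop_dc=False)
        np.testing.assert_allclose(spec.P, [0.2, 0.6, 0.2])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_any_input_sums_to_one(self, seed):
        raw = np.random.default_rng(seed).random(33) + 1e-12
        f = np.linspace(0, 50, 33)
        spec = l1_normalize(raw, f)
        assert spec.P.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(spec.P >= 0)

    def test_all_zero_flags_silent_without_dividing(self):
        spec = l1_normalize(np.zeros(16), np.linspace(0, 50, 16))
        assert bool(spec.silent) is True
        assert np.all(spec.P == 0.0)

    def test_total_power_preserved_separately(self):
        f = np.linspace(0, 50, 101)
        raw = np.exp(-f / 10)
        spec = l1_normalize(raw, f, drop_dc=False)
        assert spec.total_power == pytest.approx(raw.sum() * (f[1] - f[0]))


class TestTrim:
    def test_fraction_zero_is_identity(self):
        spec = l1_normalize(np.ones(100), np.linspace(0.5, 50, 100), drop_dc=False)
        trimmed = trim_low_frequencies(spec, 0.0)
        np.testing.assert_array_equal(trimmed.P, spec.P)

    def test_three_percent_of_100_bins_removes_3(self):
        spec = l1_normalize(np.ones(100), np.linspace(0.5, 50, 100), drop_dc=False)
        trimmed = trim_low_frequencies(spec, 0.03)
        assert trimmed.n_bins == 97
        assert trimmed.P.sum() == pytest.approx(1.0)

    def test_delta_at_lowest_bin_becomes_silent(self):
        raw = np.zeros(100)
        raw[0] = 5.0
        spec = l1_normalize(raw, np.linspace(0.5, 50, 100), drop_dc=False)
        trimmed = trim_low_frequencies(spec, 0.03)
        assert bool(trimmed.silent) is True

    def test_fraction_one_rejected(self):
        spec = l1_normalize(np.ones(10), np.linspace(1, 10, 10), drop_dc=False)
        with pytest.raises(DFFOCTError):
            trim_low_frequencies(spec, 1.0)


def _spectrum(P, f):
    return l1_normalize(np.asarray(P, dtype=float), np.asarray(f, dtype=float),
                        drop_dc=False)


class TestMoments:
    def test_delta_mean_frequency_and_zero_bandwidth(self):
        P = np.zeros(64)
        P[17] = 1.0
        f = np.linspace(0.5, 32, 64)
        spec = _spectrum(P, f)
        assert mean_frequency(spec) == pytest.approx(f[17])
        assert bandwidth_S(spec) == 0.0

    def test_uniform_mean_is_grid_midpoint(self):
        f = np.linspace(0.0, 50.0, 201)
        spec = _spectrum(np.ones_like(f), f)
        assert mean_frequency(spec) == pytest.approx(25.0)

    def test_two_point_bandwidth(self):
        f1, f2 = 4.0, 36.0
        f = np.array([f1, f2])
        spec = _spectrum([0.5, 0.5], f)
        assert bandwidth_S(spec) == pytest.approx(((f2 - f1) / 2) ** 2, rel=1e-9)

    @pytest.mark.parametrize("n", [64, 256, 1024])
    def test_uniform_bandwidth_converges_to_continuum(self, n):
        """Discrete uniform variance -> f_N^2/12 as the grid refines."""
        f_N = 50.0
        f = (np.arange(n) + 0.5) * f_N / n
        spec = _spectrum(np.ones(n), f)
        # midpoint grid: exact variance is (f_N^2/12)(1 - 1/n^2)
        assert bandwidth_S(spec) == pytest.approx(
            f_N**2 / 12 * (1 - 1 / n**2), rel=1e-12
        )
        assert bandwidth_S(spec) == pytest.approx(f_N**2 / 12, rel=2.0 / n**2)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bandwidth_identity_with_definitional_variance(self, seed):
        """P.f^2 - (P.f)^2 == sum P (f - mean)^2, the algebraic identity."""
        gen = np.random.default_rng(seed)
        P = gen.random(48)
        P /= P.sum()
        f = np.sort(gen.uniform(0, 50, 48))
        f += np.arange(48) * 1e-9  # guarantee strictly increasing
        spec = FrequencySpectrum(P=P, f=f, total_power=1.0)
        mu = float(P @ f)
        definitional = float(P @ (f - mu) ** 2)
        assert bandwidth_S(spec) == pytest.approx(definitional, rel=1e-9, abs=1e-12)

    def test_silent_spectrum_propagates_nan(self):
        spec = l1_normalize(np.zeros(8), np.linspace(1, 8, 8), drop_dc=False)
        assert np.isnan(mean_frequency(spec))
        assert np.isnan(bandwidth_S(spec))

    def test_summary_bounds(self, rng):
        P = rng.random(32)
        f = np.linspace(2.0, 50.0, 32)
        spec = _spectrum(P, f)
        s = summarize(spec)
        assert f[0] <= s.mean_frequency <= f[-1]
        assert 0 <= s.bandwidth_S <= ((f[-1] - f[0]) / 2) ** 2


def test_mean_frequency_monotone_in_relaxation_rate():
    """Region-median mean frequency strictly increases with the motility rate."""
    medians = []
    for i, rate in enumerate([1.0, 5.0, 20.0]):
        scene = MotilityScene(
            width=16, height=16, n_frames=512,
            regions=[Region(np.ones((16, 16), dtype=bool),
                            FluctuationModel("relaxation_phase", 0.4, rate, seed=30 + i))],
        )
        cube, _ = simulate_cube(scene)
        f, psd = welch_psd(cube.frames, 100.0)
        spec = trim_low_frequencies(l1_normalize(psd, f), 0.03)
        medians.append(np.median(mean_frequency(spec)))
    assert medians[0] < medians[1] < medians[2]
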