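"""HSV composition: channel bounds, clipping, running-std amplitude."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dffoct import (
    FluctuationModel,
    MotilityScene,
    PipelineConfig,
    Region,
    clip_value,
    compose,
    hue_channel,
    process_cube,
    process_stack,
    saturation_channel,
    simulate_cube,
    two_region_scene,
    value_channel,
)
from dffoct.dynimg import clip_threshold
from dffoct.errors import DFFOCTError, DegenerateRangeError, ShapeMismatchError


class TestValueChannel:
    def test_constant_trace_is_exactly_zero(self):
        assert np.all(value_channel(np.full((128, 3, 3), 1e6), 50) == 0.0)

    def test_iid_noise_recovers_sigma(self, rng):
        sigma = 2.5
        frames = sigma * rng.standard_normal((512, 24, 24))
        v = value_channel(frames, 50)
        assert v.mean() == pytest.approx(sigma, rel=0.05)

    def test_fast_sinusoid_gives_rms_amplitude(self):
        """A sinusoid much faster than the window averages to A/sqrt(2)."""
        fs, n, amp = 100.0, 512, 3.0
        t = np.arange(n) / fs
        trace = amp * np.sin(2 * np.pi * 25.0 * t)
        v = value_channel(trace[:, None, None], 50)
        assert v[0, 0] == pytest.approx(amp / np.sqrt(2), rel=0.02)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(DFFOCTError):
            value_channel(np.ones((30, 2, 2)), 50)


class TestClipValue:
    def test_exactly_one_in_1000_clipped(self, rng):
        vmap = rng.permutation(np.linspace(1.0, 2.0, 1000)).reshape(25, 40)
        clipped, thr = clip_value(vmap, 0.001)
        assert np.count_nonzero(vmap > thr) == 1
        assert clipped.max() == 1.0 and thr == np.sort(vmap.ravel())[-2]

    @given(st.integers(0, 2**32 - 1), st.sampled_from([0.001, 0.01, 0.1]))
    @settings(max_examples=25, deadline=None)
    def test_clip_count_is_floor_of_fraction(self, seed, fraction):
        vmap = np.random.default_rng(seed).permutation(2000).astype(float) + 1.0
        _, thr = clip_value(vmap.reshape(40, 50), fraction)
        assert np.count_nonzero(vmap > thr) == int(np.floor(fraction * vmap.size))

    def test_fraction_zero_is_pure_max_rescale(self, rng):
        vmap = rng.random((10, 10))
        clipped, thr = clip_value(vmap, 0.0)
        assert thr == vmap.max()
        np.testing.assert_allclose(clipped, vmap / vmap.max())

    def test_constant_positive_map_becomes_ones(self):
        clipped, _ = clip_value(np.full((5, 5), 3.0), 0.001)
        assert np.all(clipped == 1.0)

    def test_all_zero_map_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            clipped, thr = clip_value(np.zeros((5, 5)), 0.001)
        assert thr == 0.0 and np.all(clipped == 0.0)


class TestHueSaturation:
    def test_hue_endpoints_blue_low_red_high(self):
        mf = np.array([[2.0, 50.0, 26.0]])
        hue = hue_channel(mf, (2.0, 50.0))
        assert hue[0, 0] == pytest.approx(0.66)  # low frequency -> blue
        assert hue[0, 1] == pytest.approx(0.0)  # high frequency -> red
        assert hue[0, 2] == pytest.approx(0.33)  # midpoint -> green

    def test_hue_clamps_out_of_range(self):
        hue = hue_channel(np.array([0.1, 99.0]), (2.0, 50.0))
        assert hue[0] == pytest.approx(0.66) and hue[1] == pytest.approx(0.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(DegenerateRangeError):
            hue_channel(np.ones((2, 2)), (5.0, 5.0))

    def test_saturation_endpoints(self):
        sat = saturation_channel(np.array([0.0, 100.0]), (0.0, 100.0))
        assert sat[0] == pytest.approx(0.8)  # narrowband -> vivid
        assert sat[1] == pytest.approx(0.0)  # broadband -> grey

    def test_saturation_monotone_decreasing_in_bandwidth(self, rng):
        S = np.sort(rng.uniform(0, 100, 64))
        sat = saturation_channel(S, (0.0, 100.0))
        assert np.all(np.diff(sat) <= 0)


class TestCompose:
    def test_pure_red_pixel(self):
        img = compose(np.array([[0.0]]), np.array([[0.8]]), np.array([[1.0]]))
        r, g, b = img.rgb[0, 0]
        assert r > g and r > b

    def test_zero_value_renders_black(self):
        img = compose(np.full((3, 3), 0.4), np.full((3, 3), 0.5), np.zeros((3, 3)))
        assert np.all(img.rgb == 0.0)

    def test_zero_saturation_renders_grey(self):
        v = np.full((2, 2), 0.7)
        img = compose(np.full((2, 2), 0.3), np.zeros((2, 2)), v)
        for c in range(3):
            np.testing.assert_allclose(img.rgb[..., c], v)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            compose(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))


class TestProcessCube:
    def test_channel_ranges_attained_on_full_range_cube(self, tone_cube):
        cube, config, _, _ = tone_cube
        img = process_cube(cube, config)
        assert img.hue.max() == pytest.approx(0.66, abs=1e-9)
        assert img.saturation.max() == pytest.approx(0.8, abs=1e-9)
        assert img.hue.min() >= 0 and img.value.max() <= 1.0

    def test_fast_region_is_redder_than_slow_region(self):
        scene = two_region_scene(size=24, rate_slow=2.0, rate_fast=30.0, seed=5)
        cube, labels = simulate_cube(scene)
        img = process_cube(cube)
        hue_slow = np.median(img.hue[labels == 1])
        hue_fast = np.median(img.hue[labels == 2])
        assert hue_fast < hue_slow  # smaller hue angle = redder

    def test_static_scene_renders_black(self):
        scene = MotilityScene(width=8, height=8, n_frames=128)
        cube, _ = simulate_cube(scene)
        with pytest.warns(UserWarning):  # all-zero value map
            img = process_cube(cube)
        assert np.all(img.rgb == 0.0)

    def test_deterministic(self):
        scene = two_region_scene(size=10, n_frames=128)
        cube, _ = simulate_cube(scene)
        a = process_cube(cube)
        b = process_cube(cube)
        assert np.array_equal(a.rgb, b.rgb)

    def test_hue_consistency_across_seeds(self):
        """Same motility, different noise seeds -> region hue within 0.03."""
        hues = []
        for seed in (101, 202):
            scene = two_region_scene(size=16, rate_slow=3.0, rate_fast=25.0, seed=seed)
            cube, labels = simulate_cube(scene)
            img = process_cube(cube)
            hues.append([np.median(img.hue[labels == r]) for r in (1, 2)])
        assert abs(hues[0][0] - hues[1][0]) < 0.03
        assert abs(hues[0][1] - hues[1][1]) < 0.03


class TestProcessStack:
    def test_identical_cubes_give_identical_images(self):
        scene = two_region_scene(size=10, n_frames=128)
        cube, _ = simulate_cube(scene)
        imgs = process_stack([cube, cube])
        assert np.array_equal(imgs[0].rgb, imgs[1].rgb)
        assert imgs[0].channel_bounds == imgs[1].channel_bounds

    def test_shared_threshold_preserves_amplitude_ratio(self):
        scene = two_region_scene(size=10, n_frames=128)
        cube, _ = simulate_cube(scene)
        bright = type(cube)(
            (cube.frames - cube.frames.mean()) * 2.0 + cube.frames.mean(),
            cube.frame_rate,
        )
        imgs = process_stack([cube, bright])
        mask = imgs[1].value < 1.0  # away from the shared clip
        ratio = imgs[1].value[mask] / np.maximum(imgs[0].value[mask], 1e-12)
        assert np.median(ratio) == pytest.approx(2.0, rel=0.05)

    def test_single_plane_stack_matches_process_cube(self):
        scene = two_region_scene(size=10, n_frames=128)
        cube, _ = simulate_cube(scene)
        stack_img = process_stack([cube])[0]
        single_img = process_cube(cube)
        assert np.array_equal(stack_img.rgb, single_img.rgb)

    def test_inconsistent_shapes_rejected(self):
        c1, _ = simulate_cube(MotilityScene(width=8, height=8, n_frames=64))
        c2, _ = simulate_cube(MotilityScene(width=6, height=6, n_frames=64))
        with pytest.raises(ShapeMismatchError):
            process_stack([c1, c2])

    def test_pooled_clip_threshold(self, rng):
        a = rng.random(500) + 1.0
        b = rng.random(500) + 2.0
        thr = clip_threshold([a, b], 0.001)
        pooled = np.concatenate([a, b])
        assert np.count_nonzero(pooled > thr) == 1
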