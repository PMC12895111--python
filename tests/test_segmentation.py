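"""Tests of glottal segmentation, area quantification, and smoothing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phonovision import (
    Calibration,
    FrameStack,
    GlottalKinematics,
    generate_glottal_video,
)
from phonovision.segmentation import (
    SegmentationConfig,
    area_waveform,
    moving_average,
    pixel_area_scale,
    segment_glottis,
    to_grayscale,
)


class TestToGrayscale:
    def test_single_channel_identity(self):
        frame = np.random.default_rng(0).random((8, 8))
        assert to_grayscale(frame) is frame

    def test_equal_channels_reduce_to_same_value(self):
        frame = np.full((4, 4, 3), 0.37)
        assert np.allclose(to_grayscale(frame), 0.37)

    def test_pure_red_gives_luminance_weight(self):
        frame = np.zeros((4, 4, 3))
        frame[..., 0] = 1.0
        assert np.allclose(to_grayscale(frame), 0.2126)

    def test_unsupported_channel_count(self):
        with pytest.raises(ValueError, match="channel"):
            to_grayscale(np.zeros((4, 4, 2)))


def _local_mean_oracle(img: np.ndarray, block: int, offset: float) -> np.ndarray:
    """Exhaustive per-pixel threshold: mean over a symmetric-padded square
    window minus offset, evaluated pixel by pixel."""
    pad = block // 2
    padded = np.pad(img, pad, mode="symmetric")
    out = np.zeros(img.shape, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = padded[i : i + block, j : j + block]
            out[i, j] = img[i, j] < window.mean() - offset
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from skimage.measure import label

    if not mask.any():
        return mask
    labels = label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == np.argmax(counts)


class TestSegmentGlottis:
    def test_uniform_bright_frame_yields_empty_mask(self):
        mask = segment_glottis(np.full((32, 32), 0.8))
        assert not mask.any()

    def test_painted_ellipse_pixel_count_within_2pct(self):
        rr, cc = np.mgrid[0:96, 0:96]
        ellipse = ((rr - 48) / 20.0) ** 2 + ((cc - 48) / 12.0) ** 2 <= 1.0
        frame = np.where(ellipse, 0.1, 0.8)
        mask = segment_glottis(frame)
        assert abs(mask.sum() - ellipse.sum()) <= 0.02 * ellipse.sum()

    def test_only_largest_dark_component_kept(self):
        frame = np.full((64, 64), 0.8)
        frame[10:16, 10:16] = 0.1  # 36 px
        frame[30:45, 30:45] = 0.1  # 225 px
        mask = segment_glottis(frame)
        assert mask[35, 35] and not mask[12, 12]
        assert mask.sum() == 15 * 15

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_threshold_on_small_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((16, 16))
        cfg = SegmentationConfig(block_size=7, offset=0.1)
        expected = _largest_component(_local_mean_oracle(img, 7, 0.1))
        assert np.array_equal(segment_glottis(img, cfg), expected)

    @given(st.integers(0, 1000))
    def test_exhaustive_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((12, 12))
        cfg = SegmentationConfig(block_size=5, offset=0.05)
        expected = _largest_component(_local_mean_oracle(img, 5, 0.05))
        assert np.array_equal(segment_glottis(img, cfg), expected)

    def test_out_of_range_intensities_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            segment_glottis(np.full((8, 8), 2.0))


class TestPixelAreaScale:
    @pytest.mark.parametrize("scale,expected", [(0.01, 0.0001), (1.0, 1.0), (0.5, 0.25)])
    def test_square_of_scale(self, scale, expected):
        assert pixel_area_scale(Calibration(fps=1000, mm_per_pixel=scale)) == expected
        assert pixel_area_scale(scale) == expected

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            pixel_area_scale(0.0)


class TestMovingAverage:
    def test_impulse_window3(self):
        out = moving_average([0, 0, 1, 0, 0], 3)
        assert np.allclose(out, [0, 1 / 3, 1 / 3, 1 / 3, 0])

    def test_constant_unchanged_and_window1_identity(self):
        x = np.full(11, 3.5)
        assert np.allclose(moving_average(x, 7), x)
        y = np.random.default_rng(0).random(9)
        assert np.allclose(moving_average(y, 1), y)

    @pytest.mark.parametrize("window", [2, 4, 99])
    def test_invalid_windows_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), window)

    @given(st.lists(st.floats(0, 100), min_size=7, max_size=40), st.sampled_from([3, 5, 7]))
    def test_matches_bruteforce_convolution(self, values, window):
        x = np.asarray(values)
        out = moving_average(x, window)
        h = window // 2
        brute = [x[max(0, i - h) : i + h + 1].mean() for i in range(len(x))]
        assert np.allclose(out, brute, atol=1e-12)

    def test_interior_mean_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.random(200)
        w = 5
        out = moving_average(x, w)
        # on the interior the smoother is an exact windowed mean
        h = w // 2
        interior = out[h:-h]
        brute = np.convolve(x, np.ones(w) / w, mode="valid")
        assert np.allclose(interior, brute, atol=1e-12)


class TestAreaWaveform:
    def test_static_rectangle_area_exact(self):
        frame = np.full((64, 64), 0.8, dtype=np.float32)
        frame[20:30, 20:40] = 0.1  # 10 x 20 = 200 px
        stack = FrameStack(np.repeat(frame[None], 5, axis=0), Calibration())
        _, wave = area_waveform(stack)
        assert np.allclose(wave.area_raw, 0.02)
        assert np.allclose(wave.area_smooth, 0.02)

    def test_all_bright_stack_zero_waveform(self):
        stack = FrameStack(np.full((4, 32, 32), 0.8, dtype=np.float32), Calibration())
        masks, wave = area_waveform(stack)
        assert wave.area_raw.sum() == 0.0
        assert not masks.masks.any()

    def test_smoothed_area_tracks_ground_truth(self, sym_video, sym_segmented):
        _, truth = sym_video
        _, wave = sym_segmented
        err = wave.area_smooth - truth.true_area
        rel_rms = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(truth.true_area**2))
        assert rel_rms <= 0.05

    def test_noise_robustness_at_sigma_005(self, calib):
        kin = GlottalKinematics(f0=250.0, duration=0.008)
        stack, truth = generate_glottal_video(kin, calib, noise_sigma=0.05, seed=21)
        _, wave = area_waveform(stack)
        err = wave.area_smooth - truth.true_area
        rel_rms = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(truth.true_area**2))
        assert rel_rms <= 0.05

    def test_doubling_scale_quadruples_area(self):
        frame = np.full((48, 48), 0.8, dtype=np.float32)
        frame[10:20, 10:20] = 0.1
        wave1 = area_waveform(FrameStack(frame[None], Calibration(mm_per_pixel=0.01)))[1]
        wave2 = area_waveform(FrameStack(frame[None], Calibration(mm_per_pixel=0.02)))[1]
        assert np.allclose(wave2.area_raw, 4.0 * wave1.area_raw)
        assert np.allclose(wave2.area_smooth, 4.0 * wave1.area_smooth)

    def test_smooth_max_never_exceeds_raw_max(self, sym_segmented):
        _, wave = sym_segmented
        assert wave.area_smooth.max() <= wave.area_raw.max() + 1e-12
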