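"""Tests of the synthetic generators against their analytic ground truth."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phonovision import (
    Calibration,
    GlottalKinematics,
    generate_diffusion_series,
    generate_glottal_video,
    generate_livedead_image,
    generate_pressure_sweep,
)
from phonovision.signal_ops import normalized_autocorr
from phonovision.synthetic import edge_positions


class TestGlottalVideo:
    def test_static_slit_area_is_rest_gap_times_length(self, calib):
        kin = GlottalKinematics(amp_left=0.0, amp_right=0.0, rest_gap=0.3, duration=0.001)
        _, truth = generate_glottal_video(kin, calib)
        assert np.allclose(truth.true_area, 0.3 * kin.fold_length)

    @pytest.mark.parametrize(
        "fps,duration,expected",
        [(20_000, 0.02, 400), (20_000, 0.008, 160), (10_000, 0.02, 200)],
    )
    def test_frame_count_is_fps_times_duration(self, fps, duration, expected):
        kin = GlottalKinematics(duration=duration)
        stack, _ = generate_glottal_video(kin, Calibration(fps=fps, mm_per_pixel=0.01))
        assert stack.n_frames == expected

    def test_250hz_truth_has_five_cycles_in_20ms(self, calib):
        kin = GlottalKinematics(f0=250.0, duration=0.02)
        _, truth = generate_glottal_video(kin, calib)
        # closed-form period: 1/250 s = 80 frames at 20 kHz -> 5 cycles
        acf = normalized_autocorr(truth.true_area, 200)
        assert np.argmax(acf[40:200]) + 40 == 80
        crossings = np.sum(np.diff(truth.true_area > truth.true_area.mean()) != 0)
        assert crossings == pytest.approx(2 * 5, abs=1)

    def test_gap_never_negative_under_collision(self, calib):
        kin = GlottalKinematics(rest_gap=0.0, amp_left=0.5, amp_right=0.1, duration=0.004)
        _, truth = generate_glottal_video(kin, calib)
        assert np.min(truth.true_right_edge - truth.true_left_edge) >= 0.0

    def test_analytic_area_matches_rendered_row_sum(self, sym_video):
        stack, truth = sym_video
        # numerical row-sum of rendered gap widths: dark coverage per frame
        contrast = 0.8 - 0.1
        dark = (0.8 - stack.frames.astype(float)) / contrast
        rendered = dark.sum(axis=(1, 2)) * stack.calib.mm_per_pixel**2
        rel = np.abs(rendered - truth.true_area) / truth.true_area
        assert truth.true_left_edge.shape[1] >= 64
        assert rel.max() < 0.02

    def test_fixed_seed_reproducible_different_seed_not(self, calib):
        kin = GlottalKinematics(duration=0.001)
        a, _ = generate_glottal_video(kin, calib, noise_sigma=0.05, seed=7)
        b, _ = generate_glottal_video(kin, calib, noise_sigma=0.05, seed=7)
        c, _ = generate_glottal_video(kin, calib, noise_sigma=0.05, seed=8)
        assert a.frames.tobytes() == b.frames.tobytes()
        assert a.frames.tobytes() != c.frames.tobytes()

    def test_zero_phase_lag_gives_rank1_displacement(self, calib):
        kin = GlottalKinematics(ap_phase_lag=0.0, duration=0.004)
        _, truth = generate_glottal_video(kin, calib)
        disp = truth.true_right_edge - kin.rest_gap / 2.0  # (T, R) excursions
        s = np.linalg.svd(disp, compute_uv=False)
        assert s[1] / s[0] < 1e-8

    def test_oversized_glottis_raises_naming_dimension(self, calib):
        kin = GlottalKinematics(amp_left=1.0, amp_right=1.0)
        with pytest.raises(ValueError, match="width"):
            generate_glottal_video(kin, calib, image_shape=(200, 50))
        with pytest.raises(ValueError, match="height"):
            generate_glottal_video(kin, calib, image_shape=(50, 400))

    @given(
        f0=st.floats(100, 1200),
        amp_l=st.floats(0, 0.5),
        amp_r=st.floats(0, 0.5),
        lag=st.floats(0, np.pi),
    )
    def test_edge_model_gap_nonnegative_property(self, f0, amp_l, amp_r, lag):
        kin = GlottalKinematics(
            f0=f0, rest_gap=0.0, amp_left=amp_l, amp_right=amp_r,
            ap_phase_lag=lag, duration=0.002,
        )
        t = np.linspace(0, kin.duration, 50)
        yf = np.linspace(0.01, 0.99, 20)
        xl, xr = edge_positions(kin, t, yf)
        assert np.min(xr - xl) >= 0.0


class TestPressureSweep:
    def test_no_oscillation_when_amp_zero(self):
        trace = generate_pressure_sweep(3.0, 1.0, 0.0, 250.0, 5000.0, 5.0, 0.0, seed=1)
        t = trace.time
        assert np.allclose(trace.samples, 1.0 * t)
        assert trace.metadata["true_onset_pressure"] is None

    def test_oscillation_starts_at_onset_time(self):
        trace = generate_pressure_sweep(3.0, 1.0, 0.5, 250.0, 5000.0, 5.0, 0.0, seed=1)
        resid = np.abs(trace.samples - 1.0 * trace.time)
        first = trace.time[np.flatnonzero(resid > 1e-9)[0]]
        assert first == pytest.approx(3.0, abs=1.0 / 5000.0 + 1e-9)
        assert trace.metadata["true_onset_time"] == pytest.approx(3.0)

    def test_oscillation_amplitude_definition(self):
        trace = generate_pressure_sweep(1.0, 1.0, 0.5, 250.0, 5000.0, 5.0, 0.0, seed=1)
        resid = np.abs(trace.samples - 1.0 * trace.time)
        assert resid.max() == pytest.approx(0.5, rel=1e-3)

    def test_ramp_never_reaching_onset_marks_absent(self):
        trace = generate_pressure_sweep(10.0, 1.0, 0.5, 250.0, 5000.0, 2.0, 0.0, seed=1)
        assert trace.metadata["true_onset_pressure"] is None

    def test_nyquist_precondition(self):
        with pytest.raises(ValueError, match="fs"):
            generate_pressure_sweep(3.0, 1.0, 0.5, 600.0, 1000.0, 1.0)


class TestDiffusionSeries:
    def test_zero_target_has_no_stained_pixels(self):
        images, roi, true = generate_diffusion_series(1, [0.0], (64, 64), seed=0,
                                                      noise_sigma=0.0)
        assert true == [0.0]
        assert not np.any((images[0] < 0.5) & roi)

    def test_requested_fractions_met_to_one_pixel(self):
        images, roi, true = generate_diffusion_series(
            3, [0.32, 0.41, 1.0], (128, 128), seed=0, noise_sigma=0.0
        )
        n_roi = roi.sum()
        for img, target, realized in zip(images, [0.32, 0.41, 1.0], true):
            stained = int(np.sum((img < 0.5) & roi))
            assert abs(stained - target * n_roi) <= 1.0
            assert stained == round(realized * n_roi)

    def test_decreasing_targets_rejected(self):
        with pytest.raises(ValueError, match="monotone|nondecreasing"):
            generate_diffusion_series(2, [0.5, 0.3], (64, 64))


class TestLiveDeadImage:
    def test_blank_request_gives_background_only(self):
        image, truth = generate_livedead_image(0, 0, (64, 64), seed=0)
        assert truth["viability_pct"] is None
        assert image.max() < 0.2

    def test_viability_ground_truth(self):
        _, truth = generate_livedead_image(74, 26, (512, 512), seed=0)
        assert truth["viability_pct"] == pytest.approx(74.0)

    def test_fixed_seed_is_byte_identical(self):
        a, _ = generate_livedead_image(10, 10, (128, 128), seed=3)
        b, _ = generate_livedead_image(10, 10, (128, 128), seed=3)
        assert a.tobytes() == b.tobytes()

    def test_overcrowded_request_errors(self):
        with pytest.raises(RuntimeError, match="could not place"):
            generate_livedead_image(500, 500, (64, 64), blob_radius=4.0, seed=0)
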