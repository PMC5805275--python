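"""The pixel-difference engine: traces, masking, reference selection, reliability."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import cardiomotion as cm
from cardiomotion.errors import (
    CardiomotionError,
    DegenerateMaskError,
    InsufficientDataError,
    ParameterError,
    UndefinedScoreError,
)

finite_images = hnp.arrays(
    dtype=np.float64,
    shape=hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=6),
    elements=st.floats(0, 255, allow_nan=False),
)


class TestFrameDifference:
    def test_identity_is_zero(self):
        img = np.random.default_rng(0).random((5, 5))
        np.testing.assert_array_equal(
            cm.frame_difference(img, img), np.zeros((5, 5))
        )

    def test_hand_computed_example(self):
        img_i = np.array([[10.0, 20.0], [30.0, 40.0]])
        img_ref = np.array([[20.0, 20.0], [10.0, 40.0]])
        np.testing.assert_array_equal(
            cm.frame_difference(img_i, img_ref),
            np.array([[10.0, 0.0], [20.0, 0.0]]),
        )

    @settings(deadline=None, max_examples=25)
    @given(a=finite_images)
    def test_symmetric_in_arguments(self, a):
        b = np.roll(a, 1, axis=0)
        np.testing.assert_array_equal(
            cm.frame_difference(a, b), cm.frame_difference(b, a)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(CardiomotionError):
            cm.frame_difference(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMeanMaskedIntensity:
    def test_all_zero_image(self):
        assert cm.mean_masked_intensity(np.zeros((4, 4))) == 0.0

    def test_single_bright_pixel_whole_frame(self):
        img = np.zeros((4, 4))
        img[1, 2] = 8.0
        assert cm.mean_masked_intensity(img) == pytest.approx(0.5)

    def test_single_bright_pixel_masked(self):
        img = np.zeros((4, 4))
        img[1, 2] = 8.0
        mask = cm.PixelMask(img > 0)
        assert cm.mean_masked_intensity(img, mask) == pytest.approx(8.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateMaskError):
            cm.mean_masked_intensity(
                np.ones((3, 3)), cm.PixelMask(np.zeros((3, 3), dtype=bool))
            )

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(CardiomotionError):
            cm.PixelMask(np.full((2, 2), 0.5))


class TestVelocityTrace:
    def test_static_stack_all_zero(self):
        stack = cm.ImageStack(np.full((5, 8, 8), 100.0), 0.01)
        trace = cm.compute_velocity_trace(stack)
        np.testing.assert_array_equal(trace.values, np.zeros(5))
        assert trace.mode == "velocity"

    def test_single_pixel_shift_signature(self):
        """Shifted frame gives motion; repeated frame gives zero."""
        f1 = np.zeros((8, 8))
        f1[3, 2:5] = 100.0
        f2 = np.roll(f1, 1, axis=1)
        stack = cm.ImageStack(np.stack([f1, f2, f2]), 0.01)
        trace = cm.compute_velocity_trace(stack)
        assert trace.values[0] == 0.0
        assert trace.values[1] > 0.0
        assert trace.values[2] == 0.0


class TestSelectReferenceFrame:
    def test_constant_zero_trace_tie_break(self):
        trace = cm.MotionTrace(np.zeros(20), 0.01, "velocity")
        assert cm.select_reference_frame(trace, window=5) == 5

    def test_single_sharp_minimum_found(self):
        """Matches a brute-force evaluation of the windowed score."""
        rng = np.random.default_rng(11)
        v = 50.0 + rng.random(60) * 5
        v[30:41] = 1.0  # quiescent stretch
        trace = cm.MotionTrace(v, 0.01, "velocity")
        w = 5
        scores = [np.abs(v[i - w : i + w + 1]).mean() for i in range(w, 60 - w)]
        expected = int(np.argmin(scores)) + w
        assert cm.select_reference_frame(trace, window=w) == expected

    def test_short_trace_rejected(self):
        trace = cm.MotionTrace(np.zeros(5), 0.01, "velocity")
        with pytest.raises(InsufficientDataError):
            cm.select_reference_frame(trace, window=5)

    def test_reference_falls_in_quiescent_interval(self, cell_movie):
        stack, truth = cell_movie
        vel = cm.compute_velocity_trace(stack)
        ref = cm.select_reference_frame(vel)
        assert ref in truth.quiescent_frames


class TestNoiseMask:
    def test_noiseless_block_mask_equals_swept_area(self, block_movie):
        stack, truth = block_movie
        mask = cm.build_noise_mask(stack, reference_index=0)
        np.testing.assert_array_equal(mask.mask, truth.swept_pixels)

    def test_static_stack_degenerate(self):
        stack = cm.ImageStack(np.full((5, 8, 8), 42.0), 0.01)
        with pytest.raises(DegenerateMaskError):
            cm.build_noise_mask(stack, reference_index=0)

    def test_noisy_block_classification(self, block_movie):
        """CNR = 5: the mask keeps moving pixels, rejects background."""
        stack, truth = block_movie
        noisy = cm.add_noise(stack, sigma=40.0, seed=123)
        mask = cm.build_noise_mask(noisy, reference_index=0)
        swept = truth.swept_pixels
        recall = (mask.mask & swept).sum() / swept.sum()
        contamination = (mask.mask & ~swept).sum() / (~swept).sum()
        assert recall >= 0.95
        assert contamination <= 0.05


class TestDisplacementTrace:
    def test_static_stack_all_zero(self):
        stack = cm.ImageStack(np.full((4, 6, 6), 7.0), 0.01)
        trace = cm.compute_displacement_trace(stack, reference_index=0)
        np.testing.assert_array_equal(trace.values, np.zeros(4))

    def test_zero_at_reference_frame(self, cell_movie):
        stack, _ = cell_movie
        trace = cm.compute_displacement_trace(stack, reference_index=3)
        assert trace.values[3] == 0.0
        assert trace.reference_index == 3

    def test_monotone_then_saturating_in_offset(self):
        """Displacement grows with block offset, then caps at block extent."""
        stack, truth = cm.generate_block_movie(
            block_size=12, speeds=(2.0, 2.0), n_frames=61, frame_size=96
        )
        disp = cm.compute_displacement_trace(stack, reference_index=0)
        offsets = truth.offsets_px
        order = np.argsort(offsets[:15])  # outbound pass
        sub = offsets[:15][order] <= 12
        vals = disp.values[:15][order]
        assert np.all(np.diff(vals[sub]) >= 0)
        beyond = disp.values[offsets > 12]
        assert np.ptp(beyond) <= 0.01 * beyond.mean()

    def test_invalid_reference_rejected(self, cell_movie):
        stack, _ = cell_movie
        with pytest.raises(ParameterError):
            cm.compute_displacement_trace(stack, reference_index=10_000)


class TestGaussianBlur:
    def test_uniform_frame_unchanged(self):
        stack = cm.ImageStack(np.full((2, 16, 16), 55.0), 0.01)
        blurred = cm.gaussian_blur_stack(stack, 3.0)
        np.testing.assert_allclose(blurred.frames, stack.frames, atol=1e-9)

    def test_blur_then_difference_of_identical_frames_is_zero(self):
        frame = np.random.default_rng(5).random((16, 16)) * 200
        stack = cm.ImageStack(np.stack([frame, frame]), 0.01)
        blurred = cm.gaussian_blur_stack(stack, 10.0)
        np.testing.assert_array_equal(
            cm.frame_difference(blurred.frames[0], blurred.frames[1]),
            np.zeros((16, 16)),
        )

    def test_nonpositive_sigma_rejected(self):
        stack = cm.ImageStack(np.zeros((2, 4, 4)), 0.01)
        with pytest.raises(ParameterError):
            cm.gaussian_blur_stack(stack, 0.0)


class TestReliabilityCheck:
    def test_clean_cell_overlaps(self, cell_summary):
        assert cell_summary.reliability.overlap_score > 0.95
        assert not cell_summary.reliability.saturation_suspected

    def test_saturating_repetitive_cell_flagged(self, repetitive_movie):
        stack, _ = repetitive_movie
        summary = cm.analyze(stack, cm.AnalysisConfig(use_noise_mask=False))
        assert summary.reliability.saturation_suspected

    def test_blur_restores_overlap_on_repetitive_cell(self, repetitive_movie):
        stack, _ = repetitive_movie
        summary = cm.analyze(
            stack, cm.AnalysisConfig(use_noise_mask=False, blur_sigma=10.0)
        )
        assert summary.reliability.overlap_score > 0.95

    def test_flat_traces_undefined(self):
        disp = cm.MotionTrace(np.zeros(10), 0.01, "displacement",
                              reference_index=0)
        vel = cm.MotionTrace(np.zeros(10), 0.01, "velocity")
        with pytest.raises(UndefinedScoreError):
            cm.reliability_check(disp, vel)


class TestTraceInvariants:
    def test_intensity_inversion_leaves_traces_unchanged(self, cell_movie):
        """|a - b| is invariant under i -> max - i applied to every pixel."""
        stack, _ = cell_movie
        top = stack.frames.max()
        inverted = cm.ImageStack(
            top - stack.frames, stack.frame_interval, "inverted"
        )
        v1 = cm.compute_velocity_trace(stack)
        v2 = cm.compute_velocity_trace(inverted)
        np.testing.assert_allclose(v1.values, v2.values)
        d1 = cm.compute_displacement_trace(stack, 0)
        d2 = cm.compute_displacement_trace(inverted, 0)
        np.testing.assert_allclose(d1.values, d2.values)

    @settings(deadline=None, max_examples=10)
    @given(
        frames=hnp.arrays(
            dtype=np.float64,
            shape=(4, 5, 5),
            elements=st.floats(0, 255, allow_nan=False),
        )
    )
    def test_traces_always_finite_nonnegative(self, frames):
        stack = cm.ImageStack(frames, 0.01)
        for trace in (
            cm.compute_velocity_trace(stack),
            cm.compute_displacement_trace(stack, 0),
        ):
            assert np.all(np.isfinite(trace.values))
            assert np.all(trace.values >= 0)

    def test_velocity_mode_rejects_reference(self):
        with pytest.raises(CardiomotionError):
            cm.MotionTrace(np.zeros(3), 0.01, "velocity", reference_index=0)
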