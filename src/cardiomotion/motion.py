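"""Pixel-intensity-difference motion engine.

Contraction of a muscle preparation is quantified without tracking: each
frame is subtracted pixel-wise from a reference frame, the absolute
difference is averaged over the frame (or over a noise mask), and that
scalar is the motion value.  Two reference conventions give two traces:

* **displacement** — a fixed, relaxed (diastolic) reference frame; the
  trace accumulates displacement relative to diastole.
* **velocity** — the immediately preceding frame; the trace measures
  displacement per interframe interval.

Supporting steps: automatic selection of the relaxed reference frame from
the quietest stretch of the velocity trace; a noise mask built from the
maximum projection of the difference stack (threshold mean + SD) so that
only pixels moving above the noise floor contribute; an optional Gaussian
blur for preparations with repetitive spatial texture (e.g. well-organized
sarcomeres); and a reliability check comparing the differentiated
displacement trace with the velocity trace, whose divergence signals
pixel-movement saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .errors import (
    CardiomotionError,
    DegenerateMaskError,
    InsufficientDataError,
    ParameterError,
    UndefinedScoreError,
)
from .image_io import ImageStack

__all__ = [
    "MotionTrace",
    "PixelMask",
    "ReliabilityReport",
    "frame_difference",
    "mean_masked_intensity",
    "gaussian_blur_stack",
    "compute_velocity_trace",
    "compute_displacement_trace",
    "select_reference_frame",
    "build_noise_mask",
    "reliability_check",
]


@dataclass
class MotionTrace:
    """Per-frame scalar motion values with provenance.

    ``values[0]`` is 0 for a velocity trace (no predecessor) and
    ``values[reference_index]`` is 0 for a displacement trace (a frame
    differenced against itself).
    """

    values: np.ndarray
    frame_interval: float
    mode: str  # "displacement" | "velocity"
    reference_index: Optional[int] = None
    mask_applied: bool = False
    blur_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mode not in ("displacement", "velocity"):
            raise CardiomotionError(f"unknown trace mode {self.mode!r}")
        if self.mode == "velocity" and self.reference_index is not None:
            raise CardiomotionError("velocity traces have no fixed reference")
        if self.mode == "displacement" and self.reference_index is None:
            raise CardiomotionError("displacement traces need a reference index")
        if not (self.frame_interval > 0):
            raise CardiomotionError("frame_interval must be positive")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise CardiomotionError("trace values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.frame_interval


@dataclass
class PixelMask:
    """Binary image marking pixels whose motion exceeds the noise floor."""

    mask: np.ndarray
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            uniq = np.unique(self.mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise CardiomotionError("mask must be strictly binary")
            self.mask = self.mask.astype(bool)
        self.coverage = float(self.mask.mean())


@dataclass(frozen=True)
class ReliabilityReport:
    """Agreement between differentiated displacement and measured velocity.

    ``overlap_score`` is the Pearson correlation between |d(displacement)/dt|
    and the velocity trace; low values indicate pixel-movement saturation
    (moving structure no longer overlaps its reference position).
    """

    overlap_score: float
    saturation_suspected: bool


def frame_difference(img_i: np.ndarray, img_ref: np.ndarray) -> np.ndarray:
    """Absolute per-pixel difference between a frame and a reference."""
    img_i = np.asarray(img_i, dtype=np.float64)
    img_ref = np.asarray(img_ref, dtype=np.float64)
    if img_i.shape != img_ref.shape:
        raise CardiomotionError(
            f"shape mismatch: {img_i.shape} vs {img_ref.shape}"
        )
    return np.abs(img_i - img_ref)


def mean_masked_intensity(
    img: np.ndarray, mask: Optional[PixelMask] = None
) -> float:
    """Mean pixel intensity of ``img``, restricted to mask pixels if given."""
    img = np.asarray(img, dtype=np.float64)
    if mask is None:
        return float(img.mean())
    if mask.mask.shape != img.shape:
        raise CardiomotionError(
            f"mask shape {mask.mask.shape} does not match image {img.shape}"
        )
    if mask.coverage == 0:
        raise DegenerateMaskError("mask selects no pixels")
    return float(img[mask.mask].mean())


def gaussian_blur_stack(stack: ImageStack, sigma: float) -> ImageStack:
    """Blur every frame with an isotropic spatial Gaussian.

    Applied before differencing; its purpose is to suppress repetitive
    spatial texture, which is a property of the frames themselves.
    """
    if not (sigma > 0):
        raise ParameterError(f"blur sigma must be > 0, got {sigma}")
    blurred = ndimage.gaussian_filter(stack.frames, sigma=(0.0, sigma, sigma))
    return ImageStack(
        frames=blurred,
        frame_interval=stack.frame_interval,
        source_path=stack.source_path,
        bit_depth_origin=stack.bit_depth_origin,
    )


def _maybe_blur(stack: ImageStack, blur_sigma: Optional[float]) -> ImageStack:
    return gaussian_blur_stack(stack, blur_sigma) if blur_sigma else stack


def compute_velocity_trace(
    stack: ImageStack,
    mask: Optional[PixelMask] = None,
    blur_sigma: Optional[float] = None,
) -> MotionTrace:
    """Frame-to-frame motion trace (reference = previous frame).

    ``values[0]`` is defined as 0 so the trace stays length-aligned with
    the stack.
    """
    stack = _maybe_blur(stack, blur_sigma)
    frames = stack.frames
    values = np.zeros(stack.n_frames)
    for i in range(1, stack.n_frames):
        values[i] = mean_masked_intensity(
            frame_difference(frames[i], frames[i - 1]), mask
        )
    return MotionTrace(
        values=values,
        frame_interval=stack.frame_interval,
        mode="velocity",
        mask_applied=mask is not None,
        blur_sigma=blur_sigma,
    )


def compute_displacement_trace(
    stack: ImageStack,
    reference_index: int,
    mask: Optional[PixelMask] = None,
    blur_sigma: Optional[float] = None,
) -> MotionTrace:
    """Cumulative-displacement trace against a fixed reference frame."""
    if not (0 <= reference_index < stack.n_frames):
        raise ParameterError(
            f"reference index {reference_index} outside [0, {stack.n_frames - 1}]"
        )
    stack = _maybe_blur(stack, blur_sigma)
    frames = stack.frames
    ref = frames[reference_index]
    values = np.empty(stack.n_frames)
    for i in range(stack.n_frames):
        values[i] = mean_masked_intensity(frame_difference(frames[i], ref), mask)
    values[reference_index] = 0.0
    return MotionTrace(
        values=values,
        frame_interval=stack.frame_interval,
        mode="displacement",
        reference_index=reference_index,
        mask_applied=mask is not None,
        blur_sigma=blur_sigma,
    )


def select_reference_frame(velocity: MotionTrace, window: int = 5) -> int:
    """Pick the most quiescent (diastolic) frame from a velocity trace.

    Scores each fully-windowed index by the mean of |velocity| over the
    centered window of ``2 * window + 1`` frames and returns the global
    minimum (ties broken by lowest index).  The winner serves as the fixed
    reference for displacement mode.
    """
    if window < 0:
        raise ParameterError("window must be >= 0")
    v = np.abs(velocity.values)
    size = 2 * window + 1
    if len(v) < size:
        raise InsufficientDataError(
            f"velocity trace of {len(v)} frames is shorter than the "
            f"quiescence window of {size}"
        )
    # mean over each fully-contained centered window
    kernel = np.full(size, 1.0 / size)
    scores = np.convolve(v, kernel, mode="valid")
    return int(np.argmin(scores)) + window


def build_noise_mask(
    stack: ImageStack,
    reference_index: int,
    blur_sigma: Optional[float] = None,
) -> PixelMask:
    """Mask of pixels whose motion exceeds the noise floor.

    Three steps: (1) maximum projection, over the whole recording, of the
    absolute difference of each frame against the reference; (2) threshold
    that projection at its mean grey value plus one SD (strictly greater;
    population SD); (3) use the resulting binary image to restrict all
    mean-intensity computations to moving pixels.
    """
    if not (0 <= reference_index < stack.n_frames):
        raise ParameterError(
            f"reference index {reference_index} outside [0, {stack.n_frames - 1}]"
        )
    stack = _maybe_blur(stack, blur_sigma)
    frames = stack.frames
    ref = frames[reference_index]
    projection = np.zeros(stack.frame_shape)
    for i in range(stack.n_frames):
        np.maximum(projection, np.abs(frames[i] - ref), out=projection)
    if projection.max() == projection.min():
        raise DegenerateMaskError(
            "difference max-projection is uniform: no motion detected in "
            "this recording"
        )
    threshold = projection.mean() + projection.std()
    mask = projection > threshold
    if not mask.any():
        raise DegenerateMaskError(
            "no pixel exceeds the mean + SD noise threshold; no motion "
            "above noise level"
        )
    return PixelMask(mask=mask)


def reliability_check(
    displacement: MotionTrace,
    velocity: MotionTrace,
    saturation_threshold: float = 0.8,
) -> ReliabilityReport:
    """Compare |d(displacement)/dt| with the velocity trace.

    In the absence of pixel-movement saturation the two should overlap;
    their Pearson correlation is the overlap score, and a score below
    ``saturation_threshold`` flags suspected saturation.
    """
    if len(displacement) != len(velocity):
        raise CardiomotionError("traces differ in length")
    if displacement.mode != "displacement" or velocity.mode != "velocity":
        raise CardiomotionError(
            "expected one displacement and one velocity trace"
        )
    dt = displacement.frame_interval
    derived = np.abs(np.diff(displacement.values)) / dt
    measured = velocity.values[1:]
    if np.ptp(derived) == 0 or np.ptp(measured) == 0:
        raise UndefinedScoreError(
            "overlap score undefined: a trace has zero variance"
        )
    score = float(stats.pearsonr(derived, measured).statistic)
    return ReliabilityReport(
        overlap_score=score,
        saturation_suspected=score < saturation_threshold,
    )
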