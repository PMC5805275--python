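"""Shared fixtures: synthetic movies and traces reused across test modules.

Movies are generated once per session (they are deterministic) so the
expensive pipeline runs are not repeated.
"""

from __future__ import annotations

import numpy as np
import pytest

import cardiomotion as cm


@pytest.fixture(scope="session")
def cell_movie():
    """Smooth artificial cell: A = 6 px, t1 = 0.10 s, t2 = 0.20 s, 2 beats."""
    return cm.generate_cell_movie(
        amplitude_px=6.0, t1_s=0.10, t2_s=0.20, n_beats=2, rr_s=1.0,
        frame_rate=150.0,
    )


@pytest.fixture(scope="session")
def cell_summary(cell_movie):
    """Unmasked pipeline run on the smooth cell movie."""
    stack, _ = cell_movie
    return cm.analyze(stack, cm.AnalysisConfig(use_noise_mask=False))


@pytest.fixture(scope="session")
def repetitive_movie():
    """Striped cell driven past the stripe period: provokes saturation."""
    return cm.generate_cell_movie(
        amplitude_px=12.0, t1_s=0.10, t2_s=0.20, n_beats=2, rr_s=1.0,
        frame_rate=150.0, texture="repetitive",
    )


@pytest.fixture(scope="session")
def block_movie():
    """Rigid block translating out-and-back at 1 then 2 px/frame."""
    return cm.generate_block_movie(
        block_size=16, speeds=(1.0, 2.0), axis="x", n_frames=61,
        frame_size=128,
    )


def make_displacement_trace(
    values: np.ndarray, frame_interval: float, reference_index: int | None = None
) -> cm.MotionTrace:
    """Wrap raw values as a displacement-mode trace for beat-analysis tests."""
    values = np.asarray(values, dtype=float)
    if reference_index is None:
        reference_index = int(np.argmin(values))
    return cm.MotionTrace(
        values=values,
        frame_interval=frame_interval,
        mode="displacement",
        reference_index=reference_index,
    )


def beat_train_trace(
    amplitude: float,
    t1_s: float,
    t2_s: float,
    n_beats: int,
    rr_s: float,
    frame_rate: float,
    baseline: float = 0.0,
    drift_per_s: float = 0.0,
) -> tuple[cm.MotionTrace, list[float]]:
    """Directly synthesized contraction trace (no movie) with known kinetics."""
    lead = 0.5 * (rr_s - t1_s - t2_s)
    duration = 2 * lead + (n_beats - 1) * rr_s + t1_s + t2_s
    n = int(round(duration * frame_rate)) + 1
    times = np.arange(n) / frame_rate
    starts = [lead + k * rr_s for k in range(n_beats)]
    values = (
        baseline
        + drift_per_s * times
        + amplitude * cm.contraction_profile(times, t1_s, t2_s, starts)
    )
    return make_displacement_trace(values, 1.0 / frame_rate), starts
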