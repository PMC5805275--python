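"""Ground-truthed synthetic movies of moving and contracting objects.

The generators emulate the classic validation inputs for intensity-
difference contraction analysis:

* a rigid bright **block** translating back and forth at two known speeds
  (linearity of the velocity measure, and displacement saturation once the
  block no longer overlaps its reference position);
* a deforming **artificial cell** — an ellipse whose boundary contracts
  radially inward by a known amplitude (pixels) with a raised-cosine time
  course rising over t1 and relaxing over t2, repeated as a beat train at
  a set R-R interval;
* a **repetitive-texture** variant of the cell carrying an internal stripe
  pattern, which provokes pixel-movement saturation at amplitudes beyond
  the stripe period;
* additive Gaussian sensor noise and linear diastolic drift.

Every movie comes with a :class:`SyntheticGroundTruth` recording the
programmed quantities (speeds, amplitude, t1, t2, beat times, quiescent
frames, swept pixels) so recovery can be tested quantitatively.  All
outputs are integer grey levels on an 8-bit scale (stored as floats) and
reproducible bit-exactly under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .image_io import ImageStack

__all__ = [
    "SyntheticGroundTruth",
    "generate_block_movie",
    "generate_cell_movie",
    "contraction_profile",
    "add_noise",
    "write_fixture",
]

MAX_GREY = 255.0  # 8-bit synthetic intensity scale
BLOCK_INTENSITY = 200.0
CELL_INTENSITY = 200.0
STRIPE_PERIOD_PX = 5.0  # spatial period of the repetitive texture


@dataclass
class SyntheticGroundTruth:
    """Programmed inputs of a synthetic movie, for recovery testing."""

    kind: str  # "block" | "cell" | "repetitive_cell"
    frame_interval: float
    programmed_speeds: Optional[tuple[float, float]] = None
    amplitude_px: Optional[float] = None
    t1_s: Optional[float] = None
    t2_s: Optional[float] = None
    beat_times_s: list[float] = field(default_factory=list)
    peak_times_s: list[float] = field(default_factory=list)
    quiescent_frames: np.ndarray = field(default_factory=lambda: np.array([], int))
    swept_pixels: Optional[np.ndarray] = None
    offsets_px: Optional[np.ndarray] = None  # block: per-frame offset
    profile_px: Optional[np.ndarray] = None  # cell: per-frame inward motion


def _block_offsets(speeds: tuple[float, float], n_frames: int) -> np.ndarray:
    """Back-and-forth trajectory: out and back at each speed in turn.

    One hold frame at every turnaround so the trajectory contains true
    zero-motion frames.  Trailing frames (rounding remainder) hold at home.
    """
    seg = (n_frames - 5) // 4
    if seg < 1:
        raise ParameterError(
            f"n_frames={n_frames} is too short for an out-and-back pass at "
            "each of two speeds (need >= 9)"
        )
    offsets = [0.0]
    for s in speeds:
        for _ in range(seg):
            offsets.append(offsets[-1] + s)
        offsets.append(offsets[-1])  # hold at apex
        for _ in range(seg):
            offsets.append(offsets[-1] - s)
        offsets.append(offsets[-1])  # hold at home
    while len(offsets) < n_frames:
        offsets.append(offsets[-1])
    return np.array(offsets[:n_frames])


def generate_block_movie(
    block_size: int = 16,
    speeds: tuple[float, float] = (1.0, 2.0),
    axis: str = "x",
    n_frames: int = 61,
    frame_size: int = 128,
    margin: int = 4,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Bright rigid block on a dark background, translating at two speeds.

    The block moves out and back at ``speeds[0]``, then out and back at
    ``speeds[1]``, along ``axis`` ("x", "y", or "xy" for diagonal motion).
    Rendering is integer-snapped (offsets are rounded to whole pixels) so
    the difference signal is exactly proportional to the offset.
    """
    if axis not in ("x", "y", "xy"):
        raise ParameterError(f"axis must be x, y or xy, got {axis!r}")
    if min(speeds) <= 0:
        raise ParameterError(f"speeds must be positive, got {speeds}")
    if block_size <= 0 or block_size >= frame_size:
        raise ParameterError("block must be smaller than the frame")

    offsets = _block_offsets(speeds, n_frames)
    max_off = int(np.ceil(offsets.max()))
    if margin + block_size + max_off > frame_size:
        raise ParameterError(
            f"block would exit the frame: peak offset {max_off} px plus "
            f"block {block_size} px exceeds frame {frame_size} px"
        )

    frames = np.zeros((n_frames, frame_size, frame_size))
    swept = np.zeros((frame_size, frame_size), dtype=bool)
    for i, off in enumerate(offsets):
        o = int(round(off))
        r0 = margin + (o if axis in ("y", "xy") else 0)
        c0 = margin + (o if axis in ("x", "xy") else 0)
        frames[i, r0 : r0 + block_size, c0 : c0 + block_size] = BLOCK_INTENSITY
        swept[r0 : r0 + block_size, c0 : c0 + block_size] = True

    quiescent = np.nonzero(np.diff(offsets, prepend=offsets[0]) == 0)[0]
    truth = SyntheticGroundTruth(
        kind="block",
        frame_interval=0.01,
        programmed_speeds=tuple(speeds),
        quiescent_frames=quiescent,
        swept_pixels=swept,
        offsets_px=offsets,
    )
    stack = ImageStack(
        frames=frames,
        frame_interval=truth.frame_interval,
        source_path=f"synthetic:block(speeds={speeds},axis={axis})",
    )
    return stack, truth


def contraction_profile(
    times: np.ndarray,
    t1_s: float,
    t2_s: float,
    beat_times_s: Sequence[float],
) -> np.ndarray:
    """Normalized contraction time course: 0 at rest, 1 at peak.

    Raised-cosine ramp up over ``t1_s`` and down over ``t2_s`` from each
    beat onset; a smooth canonical profile with well-defined onset, peak,
    and full-relaxation times.
    """
    times = np.asarray(times, dtype=float)
    p = np.zeros_like(times)
    for t0 in beat_times_s:
        s = times - t0
        up = (s >= 0) & (s < t1_s)
        p[up] = np.maximum(p[up], 0.5 * (1 - np.cos(np.pi * s[up] / t1_s)))
        down = (s >= t1_s) & (s <= t1_s + t2_s)
        p[down] = np.maximum(
            p[down], 0.5 * (1 + np.cos(np.pi * (s[down] - t1_s) / t2_s))
        )
    return p


def _render_cell_frame(
    frame_size: int,
    radii: tuple[float, float],
    inward_px: float,
    texture: str,
) -> np.ndarray:
    """One frame of the artificial cell, anti-aliased at the boundary.

    The body is an ellipse whose semi-axes are both reduced by
    ``inward_px``; interior texture (if any) contracts with the material so
    stripes displace proportionally to radius.
    """
    a0, b0 = radii
    a, b = a0 - inward_px, b0 - inward_px
    c = (frame_size - 1) / 2.0
    y, x = np.mgrid[0:frame_size, 0:frame_size]
    dx, dy = x - c, y - c
    f = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    # signed distance to the ellipse boundary, in pixels (first order)
    grad = np.sqrt(dx**2 / a**4 + dy**2 / b**4)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(grad > 0, (1.0 - f) * f / grad, min(a, b))
    coverage = np.clip(dist + 0.5, 0.0, 1.0)

    if texture == "smooth":
        body = CELL_INTENSITY
    elif texture == "repetitive":
        # material x-coordinate before deformation: stripes move with the body
        sx = a / a0
        mx = dx / sx
        stripes = 0.5 * (1 + np.sin(2 * np.pi * mx / STRIPE_PERIOD_PX))
        body = 60.0 + 140.0 * stripes
    else:
        raise ParameterError(f"texture must be smooth or repetitive, got {texture!r}")
    return body * coverage


def generate_cell_movie(
    amplitude_px: float = 6.0,
    t1_s: float = 0.10,
    t2_s: float = 0.20,
    n_beats: int = 2,
    rr_s: float = 1.0,
    frame_rate: float = 150.0,
    texture: str = "smooth",
    noise_sigma: float = 0.0,
    baseline_drift: float = 0.0,
    frame_size: int = 128,
    radii: tuple[float, float] = (42.0, 34.0),
    seed: int = 0,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Deforming artificial cell with programmed beat kinetics.

    An ellipse of semi-axes ``radii`` contracts radially inward by
    ``amplitude_px`` following a raised-cosine time course (up ``t1_s``,
    down ``t2_s``), ``n_beats`` times at period ``rr_s``.  Beats are
    centered in their period so the movie starts and ends quiescent.
    Optional additive Gaussian noise (SD ``noise_sigma`` grey levels) and a
    linear diastolic intensity drift (grey levels per second).
    """
    if t1_s <= 0 or t2_s <= 0 or rr_s <= 0:
        raise ParameterError("t1, t2 and rr must be positive")
    if n_beats > 0 and t1_s + t2_s >= rr_s:
        raise ParameterError(
            f"kinetics do not fit the beat period: t1+t2 = {t1_s + t2_s} s "
            f">= rr = {rr_s} s"
        )
    if t1_s * frame_rate < 3:
        raise ParameterError(
            f"frame rate {frame_rate}/s undersamples the upstroke: t1 = "
            f"{t1_s} s spans fewer than 3 frames"
        )
    if amplitude_px <= 0 or amplitude_px >= 0.8 * min(radii):
        raise ParameterError(
            f"amplitude {amplitude_px} px must be positive and well below "
            f"the smallest semi-axis ({min(radii)} px)"
        )

    dt = 1.0 / frame_rate
    lead = 0.5 * (rr_s - t1_s - t2_s)
    if n_beats > 0:
        duration = 2 * lead + (n_beats - 1) * rr_s + t1_s + t2_s
        beat_starts = [lead + k * rr_s for k in range(n_beats)]
    else:
        duration = max(2 * dt, rr_s)
        beat_starts = []
    n_frames = max(2, int(round(duration / dt)) + 1)
    times = np.arange(n_frames) * dt

    profile = contraction_profile(times, t1_s, t2_s, beat_starts)
    inward = amplitude_px * profile

    frames = np.empty((n_frames, frame_size, frame_size))
    # render unique deformation levels once (quiescent frames all share 0)
    cache: dict[float, np.ndarray] = {}
    for i, d in enumerate(inward):
        key = round(float(d), 6)
        if key not in cache:
            cache[key] = _render_cell_frame(frame_size, radii, d, texture)
        frames[i] = cache[key]

    if baseline_drift != 0.0:
        frames = frames + baseline_drift * times[:, None, None]
    frames = np.round(np.clip(frames, 0.0, MAX_GREY))

    stack = ImageStack(
        frames=frames,
        frame_interval=dt,
        source_path=(
            f"synthetic:cell(A={amplitude_px},t1={t1_s},t2={t2_s},"
            f"texture={texture})"
        ),
    )
    if noise_sigma > 0:
        stack = add_noise(stack, noise_sigma, seed)

    truth = SyntheticGroundTruth(
        kind="cell" if texture == "smooth" else "repetitive_cell",
        frame_interval=dt,
        amplitude_px=amplitude_px,
        t1_s=t1_s,
        t2_s=t2_s,
        beat_times_s=beat_starts,
        peak_times_s=[t0 + t1_s for t0 in beat_starts],
        quiescent_frames=np.nonzero(profile == 0)[0],
        profile_px=inward,
    )
    return stack, truth


def add_noise(stack: ImageStack, sigma: float, seed: int) -> ImageStack:
    """Additive zero-mean Gaussian pixel noise, clipped to the valid range.

    Deterministic under a fixed seed; ``sigma = 0`` returns the stack
    unchanged (bit-identical frames).
    """
    if sigma < 0:
        raise ParameterError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return stack
    rng = np.random.default_rng(seed)
    top = float(2**stack.bit_depth_origin - 1)
    noisy = np.clip(
        stack.frames + rng.normal(0.0, sigma, stack.frames.shape), 0.0, top
    )
    return ImageStack(
        frames=noisy,
        frame_interval=stack.frame_interval,
        source_path=stack.source_path + f"+noise(sigma={sigma},seed={seed})",
        bit_depth_origin=stack.bit_depth_origin,
    )


def write_fixture(
    stack: ImageStack, truth: SyntheticGroundTruth, path: str | Path
) -> tuple[Path, Path]:
    """Write a movie as multi-page TIFF plus a tab-separated ground-truth sidecar."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), stack.frames.astype(np.uint8))

    sidecar = path.with_suffix(".truth.tsv")
    lines = [
        f"kind\t{truth.kind}",
        f"frame_interval_s\t{truth.frame_interval}",
    ]
    if truth.programmed_speeds is not None:
        lines.append(
            "speeds_px_per_frame\t"
            + ",".join(str(s) for s in truth.programmed_speeds)
        )
    for name, val in (
        ("amplitude_px", truth.amplitude_px),
        ("t1_s", truth.t1_s),
        ("t2_s", truth.t2_s),
    ):
        if val is not None:
            lines.append(f"{name}\t{val}")
    if truth.beat_times_s:
        lines.append("beat_times_s\t" + ",".join(f"{t:g}" for t in truth.beat_times_s))
    lines.append(
        "quiescent_frames\t" + ",".join(str(i) for i in truth.quiescent_frames)
    )
    lines.append("")
    per_frame = (
        truth.offsets_px if truth.offsets_px is not None else truth.profile_px
    )
    if per_frame is not None:
        lines.append("frame\tprogrammed_motion_px")
        for i, v in enumerate(per_frame):
            lines.append(f"{i}\t{v:.6g}")
    sidecar.write_text("\n".join(lines) + "\n")
    return path, sidecar
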