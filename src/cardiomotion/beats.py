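"""Beat segmentation and per-beat kinetic parameters.

A contraction (cumulative-displacement) trace is decomposed into beats, and
each beat yields the kinetics of interest in cardiac phenotyping: amplitude
of contraction (A), time-to-peak (t1), relaxation time (t2), contraction
duration (t1 + t2 under this module's onset/end convention), peak time, and
the R-R interval to the next beat.

Onset and end are defined operationally: a beat is a maximal excursion of
the trace above ``baseline + threshold_fraction * (max - baseline)``; the
onset is the last crossing of that level before the peak, walked back to
the nearest local minimum, and the end is the symmetric forward walk.  The
threshold fraction (default 0.10) is configurable and logged.

Baselines come in two flavours.  The global baseline is a low percentile of
the whole trace, robust for well-separated beats.  *Fast mode* instead
takes, per beat, the local minimum of the inter-beat interval immediately
preceding the onset — necessary at high contraction rates where the trace
approaches a sinusoid and never dwells at a common diastolic level, or when
the diastolic level drifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import CardiomotionError, InsufficientBeatsError
from .motion import MotionTrace

logger = logging.getLogger(__name__)

__all__ = [
    "BeatSegment",
    "BeatParameters",
    "RhythmStatistics",
    "estimate_baseline",
    "detect_beats",
    "extract_beat_parameters",
    "align_beats",
    "rhythm_statistics",
]


@dataclass
class BeatSegment:
    """One beat's frame-index span and the baseline it is measured against."""

    onset_index: int
    peak_index: int
    end_index: int
    baseline_value: float

    def __post_init__(self) -> None:
        if not (self.onset_index < self.peak_index < self.end_index):
            raise CardiomotionError(
                f"malformed beat segment: onset {self.onset_index}, "
                f"peak {self.peak_index}, end {self.end_index}"
            )


@dataclass
class BeatParameters:
    """Per-beat kinetics, all durations in seconds, amplitude in trace units."""

    amplitude: float
    time_to_peak: float
    relaxation_time: float
    contraction_duration: float
    peak_time: float
    rr_interval: Optional[float] = None

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise CardiomotionError(f"non-positive amplitude {self.amplitude}")
        if min(self.time_to_peak, self.relaxation_time) <= 0:
            raise CardiomotionError("beat durations must be positive")
        if self.contraction_duration < self.time_to_peak:
            raise CardiomotionError(
                "contraction duration shorter than time-to-peak"
            )


@dataclass(frozen=True)
class RhythmStatistics:
    """Rate and regularity over successive peak-to-peak intervals."""

    beat_rate: float  # beats per minute
    rr_mean: float  # seconds
    rr_cv: float  # SD / mean of the R-R intervals


def estimate_baseline(
    trace: MotionTrace,
    fast_mode: bool = False,
    beats: Optional[Sequence[BeatSegment]] = None,
    percentile: float = 5.0,
) -> float | np.ndarray:
    """Diastolic baseline of a contraction trace.

    Normal mode returns one global value, the ``percentile``-th percentile
    of the trace.  Fast mode requires the detected beats and returns one
    baseline per beat: the local minimum of the inter-beat interval
    immediately preceding the onset — which is exactly where the onset
    walk-back of :func:`detect_beats` lands, so the trace value at each
    onset is used.
    """
    if trace.mode != "displacement":
        raise CardiomotionError("baseline is defined on the contraction trace")
    v = trace.values
    if np.ptp(v) == 0:
        logger.info("trace is constant; no beats, baseline = %g", v[0])
        return float(v[0])
    if not fast_mode:
        return float(np.percentile(v, percentile))
    if beats is None:
        raise CardiomotionError("fast mode needs the detected beats")
    return np.array([v[b.onset_index] for b in beats], dtype=float)


def apply_fast_baselines(
    trace: MotionTrace, beats: Sequence[BeatSegment]
) -> list[BeatSegment]:
    """Re-baseline each beat to its preceding inter-beat local minimum."""
    locals_ = estimate_baseline(trace, fast_mode=True, beats=beats)
    return [
        BeatSegment(b.onset_index, b.peak_index, b.end_index, float(bl))
        for b, bl in zip(beats, np.atleast_1d(locals_))
    ]


def _walk_to_local_min(v: np.ndarray, start: int, step: int) -> int:
    """Follow a strictly descending trace from ``start`` in direction ``step``."""
    i = start
    while 0 < i < len(v) - 1 and v[i + step] < v[i]:
        i += step
    return i


def detect_beats(
    trace: MotionTrace,
    baseline: float,
    threshold_fraction: float = 0.10,
    min_rr: float = 0.25,
) -> list[BeatSegment]:
    """Segment a contraction trace into beats.

    Peaks closer than ``min_rr`` seconds to a larger peak are suppressed
    (default 0.25 s, a 240 bpm ceiling — raise it for zebrafish or other
    high-rate preparations).
    """
    if trace.mode != "displacement":
        raise CardiomotionError("beat detection runs on the contraction trace")
    if not (0 < threshold_fraction < 1):
        raise CardiomotionError(
            f"threshold_fraction must be in (0, 1), got {threshold_fraction}"
        )
    v = trace.values
    excursion = v.max() - baseline
    if excursion <= 0 or np.ptp(v) == 0:
        return []
    level = baseline + threshold_fraction * excursion
    distance = max(1, int(round(min_rr / trace.frame_interval)))
    peaks, _ = find_peaks(v, height=level, distance=distance)

    segments: list[BeatSegment] = []
    for p in peaks:
        # last sub-level sample before the peak, then back to the local minimum
        below = np.nonzero(v[: p + 1] < level)[0]
        if len(below) == 0:
            continue  # trace never below level before this peak: truncated
        onset = _walk_to_local_min(v, int(below[-1]), -1)
        above = np.nonzero(v[p:] < level)[0]
        if len(above) == 0:
            continue  # never relaxes below level after the peak: truncated
        end = _walk_to_local_min(v, int(p + above[0]), +1)
        if onset < p < end:
            segments.append(
                BeatSegment(
                    onset_index=onset,
                    peak_index=int(p),
                    end_index=end,
                    baseline_value=float(baseline),
                )
            )
    return segments


def extract_beat_parameters(
    trace: MotionTrace, beats: Sequence[BeatSegment]
) -> list[BeatParameters]:
    """Kinetic parameters per beat.

    Beats whose segment touches the first or last frame are truncated by
    the recording edges; they are dropped and logged.
    """
    v = trace.values
    dt = trace.frame_interval
    n = len(v)
    kept: list[BeatSegment] = []
    for b in beats:
        if b.onset_index <= 0 or b.end_index >= n - 1:
            logger.warning(
                "dropping beat at frame %d: truncated by recording edge",
                b.peak_index,
            )
            continue
        kept.append(b)

    params: list[BeatParameters] = []
    for k, b in enumerate(kept):
        rr = None
        if k + 1 < len(kept):
            rr = (kept[k + 1].peak_index - b.peak_index) * dt
        params.append(
            BeatParameters(
                amplitude=float(v[b.peak_index] - b.baseline_value),
                time_to_peak=(b.peak_index - b.onset_index) * dt,
                relaxation_time=(b.end_index - b.peak_index) * dt,
                contraction_duration=(b.end_index - b.onset_index) * dt,
                peak_time=b.peak_index * dt,
                rr_interval=rr,
            )
        )
    return params


def align_beats(
    trace: MotionTrace, beats: Sequence[BeatSegment]
) -> list[np.ndarray]:
    """Baseline-subtracted per-beat segments re-indexed from each onset.

    The overlay of these series is the standard visual check that beats in
    a recording share one contraction profile.
    """
    v = trace.values
    return [
        v[b.onset_index : b.end_index + 1] - b.baseline_value for b in beats
    ]


def rhythm_statistics(
    beats: Sequence[BeatSegment], frame_interval: float
) -> RhythmStatistics:
    """Beat rate and R-R regularity from successive peak times."""
    if len(beats) < 2:
        raise InsufficientBeatsError(
            f"rate needs at least 2 beats, got {len(beats)}"
        )
    peak_times = np.array([b.peak_index for b in beats]) * frame_interval
    rr = np.diff(peak_times)
    rr_mean = float(rr.mean())
    return RhythmStatistics(
        beat_rate=60.0 / rr_mean,
        rr_mean=rr_mean,
        rr_cv=float(rr.std() / rr_mean),
    )
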