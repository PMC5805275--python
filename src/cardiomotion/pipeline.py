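"""End-to-end analysis pipeline: recording in, traces + beat table out.

The canonical sequence is: load → (optional Gaussian blur) → velocity
trace → automatic reference-frame selection → noise mask → masked
displacement and velocity traces → reliability check → baseline, beat
segmentation, per-beat parameters → result files.  ``analyze`` runs it for
one recording, ``analyze_batch`` for many, tolerating per-recording
failures.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import beats as beats_mod
from . import motion
from .errors import (
    CardiomotionError,
    DegenerateMaskError,
    InsufficientBeatsError,
    ParameterError,
)
from .image_io import ImageStack, RegionOfInterest, load_stack, write_results

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunSummary", "analyze", "analyze_batch"]


@dataclass
class AnalysisConfig:
    """All tunable parameters of one analysis run.

    Defaults are logged verbatim into the run log so a run can be
    reproduced from its log alone.
    """

    frame_interval_s: Optional[float] = None
    roi: Optional[RegionOfInterest] = None
    frame_range: Optional[tuple[int, int]] = None
    blur_sigma: Optional[float] = None  # 10 recommended for repetitive texture
    use_noise_mask: bool = True
    mask_failure_hard: bool = False
    fast_mode: bool = False
    threshold_fraction: float = 0.10
    min_rr_s: float = 0.25
    baseline_percentile: float = 5.0
    reference_window_frames: int = 5
    saturation_score_threshold: float = 0.8
    output_dir: Optional[Path] = None
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction < 1):
            raise ParameterError("threshold_fraction must be in (0, 1)")
        if self.min_rr_s <= 0:
            raise ParameterError("min_rr_s must be positive")
        if not (0 <= self.baseline_percentile <= 50):
            raise ParameterError("baseline_percentile must be in [0, 50]")
        if self.reference_window_frames < 0:
            raise ParameterError("reference_window_frames must be >= 0")
        if self.blur_sigma is not None and self.blur_sigma <= 0:
            raise ParameterError("blur_sigma must be positive when set")
        if not (-1 <= self.saturation_score_threshold <= 1):
            raise ParameterError("saturation_score_threshold must be in [-1, 1]")

    def log_dict(self) -> dict[str, object]:
        d = dataclasses.asdict(self)
        d["roi"] = repr(self.roi) if self.roi else "full-frame"
        return d


@dataclass
class RunSummary:
    """Everything ``analyze`` learned about one recording."""

    files: dict[str, Path]
    reliability: Optional[motion.ReliabilityReport]
    rhythm: Optional[beats_mod.RhythmStatistics]
    beat_parameters: list[beats_mod.BeatParameters]
    reference_index: int
    mask_coverage: Optional[float]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_beats(self) -> int:
        return len(self.beat_parameters)


def analyze(
    source: Union[str, Path, ImageStack],
    config: Optional[AnalysisConfig] = None,
) -> RunSummary:
    """Run the full contraction analysis on one recording.

    ``source`` may be a path (TIFF stack, image directory, AVI/MP4) or an
    in-memory :class:`ImageStack`.  Results are written to
    ``config.output_dir`` when set; otherwise only the in-memory summary is
    returned.
    """
    config = config or AnalysisConfig()
    warnings: list[str] = []

    if isinstance(source, ImageStack):
        stack = source
        if config.frame_range or config.roi:
            if config.frame_range:
                a, b = config.frame_range
                stack = ImageStack(
                    stack.frames[a : b + 1],
                    stack.frame_interval,
                    stack.source_path,
                    stack.bit_depth_origin,
                )
            if config.roi:
                stack = stack.crop(config.roi)
    else:
        stack = load_stack(
            source,
            frame_interval=config.frame_interval_s,
            roi=config.roi,
            frame_range=config.frame_range,
        )

    velocity = motion.compute_velocity_trace(stack, blur_sigma=config.blur_sigma)
    reference = motion.select_reference_frame(
        velocity, window=config.reference_window_frames
    )

    mask = None
    if config.use_noise_mask:
        try:
            mask = motion.build_noise_mask(
                stack, reference, blur_sigma=config.blur_sigma
            )
        except DegenerateMaskError as exc:
            if config.mask_failure_hard:
                raise
            msg = f"noise mask degenerate ({exc}); continuing unmasked"
            warnings.append(msg)
            logger.warning(msg)

    if mask is not None:
        velocity = motion.compute_velocity_trace(
            stack, mask=mask, blur_sigma=config.blur_sigma
        )
    displacement = motion.compute_displacement_trace(
        stack, reference, mask=mask, blur_sigma=config.blur_sigma
    )

    reliability: Optional[motion.ReliabilityReport] = None
    try:
        reliability = motion.reliability_check(
            displacement, velocity, config.saturation_score_threshold
        )
        if reliability.saturation_suspected:
            msg = (
                "reliability check: differentiated displacement and velocity "
                f"overlap poorly (r = {reliability.overlap_score:.3f}); "
                "pixel-movement saturation suspected"
            )
            warnings.append(msg)
            logger.warning(msg)
    except CardiomotionError as exc:
        warnings.append(f"reliability score undefined: {exc}")

    baseline = beats_mod.estimate_baseline(
        displacement, percentile=config.baseline_percentile
    )
    segments = beats_mod.detect_beats(
        displacement,
        baseline=float(baseline),
        threshold_fraction=config.threshold_fraction,
        min_rr=config.min_rr_s,
    )
    if config.fast_mode and segments:
        segments = beats_mod.apply_fast_baselines(displacement, segments)
    params = beats_mod.extract_beat_parameters(displacement, segments)
    if not segments:
        warnings.append("no contraction detected (zero beats)")

    rhythm: Optional[beats_mod.RhythmStatistics] = None
    try:
        rhythm = beats_mod.rhythm_statistics(segments, stack.frame_interval)
    except InsufficientBeatsError:
        pass

    files: dict[str, Path] = {}
    if config.output_dir is not None:
        log = dict(config.log_dict())
        log["reference_frame"] = reference
        log["mask_coverage"] = mask.coverage if mask else "none"
        if reliability:
            log["reliability_overlap_score"] = f"{reliability.overlap_score:.6f}"
            log["saturation_suspected"] = reliability.saturation_suspected
        for i, w in enumerate(warnings):
            log[f"warning_{i}"] = w
        files = write_results(
            displacement,
            velocity,
            params,
            config.output_dir,
            make_plots=config.make_plots,
            log_entries=log,
            aligned_beats=beats_mod.align_beats(displacement, segments),
        )

    return RunSummary(
        files=files,
        reliability=reliability,
        rhythm=rhythm,
        beat_parameters=params,
        reference_index=reference,
        mask_coverage=mask.coverage if mask else None,
        warnings=warnings,
    )


def analyze_batch(
    sources: Sequence[Union[str, Path]],
    config: AnalysisConfig,
    out_root: Union[str, Path],
) -> tuple[dict[str, RunSummary], dict[str, str]]:
    """Analyze many recordings; one failure does not abort the batch.

    Each recording's results land in ``out_root/<recording-name>/``; a
    combined per-beat table (``combined-results.txt``, with a recording
    column) is written at the root.  Returns (summaries, failures) keyed by
    recording name.
    """
    if not sources:
        raise ParameterError("batch needs at least one input")
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)

    summaries: dict[str, RunSummary] = {}
    failures: dict[str, str] = {}
    combined_rows: list[str] = []
    for src in sources:
        name = Path(src).stem or Path(src).name
        sub_config = dataclasses.replace(config, output_dir=out_root / name)
        try:
            summary = analyze(src, sub_config)
        except CardiomotionError as exc:
            failures[name] = str(exc)
            logger.error("recording %s failed: %s", name, exc)
            continue
        summaries[name] = summary
        for i, b in enumerate(summary.beat_parameters):
            rr = "" if b.rr_interval is None else f"{b.rr_interval:.8g}"
            combined_rows.append(
                "\t".join(
                    [
                        name,
                        str(i),
                        f"{b.peak_time:.8g}",
                        f"{b.amplitude:.8g}",
                        f"{b.time_to_peak:.8g}",
                        f"{b.relaxation_time:.8g}",
                        f"{b.contraction_duration:.8g}",
                        rr,
                    ]
                )
            )

    header = (
        "recording\tbeat_index\tpeak_time_s\tamplitude_au\ttime_to_peak_s\t"
        "relaxation_time_s\tcontraction_duration_s\trr_interval_s"
    )
    (out_root / "combined-results.txt").write_text(
        "\n".join([header] + combined_rows) + "\n"
    )
    return summaries, failures
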