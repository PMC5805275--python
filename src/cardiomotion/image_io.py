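"""Loading and writing of time-lapse recordings and result files.

Recordings of beating cardiac preparations arrive as multi-page TIFF
stacks, directories of numbered image files, or AVI/MP4 containers.  All
are normalized to an :class:`ImageStack`: a ``(frame, row, column)`` array
of real-valued intensities on the source bit scale (8-bit data stays 0-255,
16-bit stays 0-65535), with a constant frame interval in seconds.

Result writing follows a fixed file contract: three tab-separated text
files (``contraction.txt``, ``speed-of-contraction.txt``,
``overview-results.txt``), optional PNG trace plots, and a plain-text run
log.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .errors import (
    BoundsError,
    InputFormatError,
    InsufficientDataError,
    MissingMetadataError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .beats import BeatParameters
    from .motion import MotionTrace

logger = logging.getLogger(__name__)

#: File suffixes treated as still images when scanning a directory.
IMAGE_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp"}

#: Suffixes that imply lossy compression; accepted with a logged warning
#: because compression artifacts inflate frame differences.
LOSSY_SUFFIXES = {".jpg", ".jpeg", ".mp4", ".avi", ".mov"}

RESULT_CONTRACTION = "contraction.txt"
RESULT_VELOCITY = "speed-of-contraction.txt"
RESULT_OVERVIEW = "overview-results.txt"
RESULT_LOG = "analysis-log.txt"

OVERVIEW_COLUMNS = (
    "beat_index",
    "peak_time_s",
    "amplitude_au",
    "time_to_peak_s",
    "relaxation_time_s",
    "contraction_duration_s",
    "rr_interval_s",
)


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular crop, 0-based, half-open bounds."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise BoundsError(
                f"degenerate ROI: rows [{self.row_start}, {self.row_end}), "
                f"cols [{self.col_start}, {self.col_end})"
            )
        if min(self.row_start, self.col_start) < 0:
            raise BoundsError("ROI bounds must be non-negative")

    def validate_against(self, shape: tuple[int, int]) -> None:
        if self.row_end > shape[0] or self.col_end > shape[1]:
            raise BoundsError(
                f"ROI {self} exceeds frame shape {shape[0]}x{shape[1]}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_start, self.row_end),
            slice(self.col_start, self.col_end),
        )


@dataclass
class ImageStack:
    """An ordered stack of scalar-intensity frames with a fixed frame interval.

    Parameters
    ----------
    frames
        ``(n_frames, rows, cols)`` float array, finite and non-negative.
    frame_interval
        Seconds per frame, strictly positive.
    source_path
        Provenance string (file path or a description for synthetic data).
    bit_depth_origin
        Bits of the source data; intensities stay on that scale.
    """

    frames: np.ndarray
    frame_interval: float
    source_path: str = ""
    bit_depth_origin: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise InputFormatError(
                f"expected (frame, row, col) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InsufficientDataError(
                f"a recording needs at least 2 frames, got {self.frames.shape[0]}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise InputFormatError("pixel intensities must be finite")
        if np.any(self.frames < 0):
            raise InputFormatError("pixel intensities must be non-negative")
        if not (self.frame_interval > 0):
            raise MissingMetadataError(
                f"frame interval must be > 0 s, got {self.frame_interval}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def crop(self, roi: RegionOfInterest) -> "ImageStack":
        roi.validate_against(self.frame_shape)
        rs, cs = roi.slices()
        return ImageStack(
            frames=self.frames[:, rs, cs].copy(),
            frame_interval=self.frame_interval,
            source_path=self.source_path,
            bit_depth_origin=self.bit_depth_origin,
        )


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Collapse a trailing color axis by the arithmetic mean of channels.

    Already-scalar input is returned unchanged (idempotent).  A 4th (alpha)
    channel, when present, is ignored.
    """
    frames = np.asarray(frames)
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        return frames[..., :3].mean(axis=-1)
    raise InputFormatError(
        f"cannot interpret array of shape {frames.shape} as an image stack"
    )


def _natural_key(name: str) -> tuple:
    """Sort key that orders frame_2 before frame_10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p.lower() for p in parts)


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    if arr.dtype == np.uint32:
        return 32
    if np.issubdtype(arr.dtype, np.integer):
        return int(arr.dtype.itemsize * 8)
    return 8  # float sources: assume 8-bit-like scale


def _read_tiff(path: Path) -> np.ndarray:
    import tifffile

    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise InputFormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def _read_directory(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise InputFormatError(f"no image files found in directory {path}")
    frames = []
    for f in files:
        try:
            frames.append(np.asarray(iio.imread(str(f))))
        except Exception as exc:  # noqa: BLE001
            raise InputFormatError(f"cannot read image {f}: {exc}") from exc
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise InputFormatError(
            f"frames in {path} have inconsistent shapes: {sorted(shapes)}"
        )
    return np.stack(frames)


def _read_video(path: Path) -> tuple[np.ndarray, float | None]:
    """Read a video container; returns (frames, fps or None)."""
    import imageio.v3 as iio

    try:
        arr = np.asarray(iio.imread(str(path), index=None))
        meta = iio.immeta(str(path))
    except Exception as exc:  # noqa: BLE001
        raise InputFormatError(
            f"cannot decode video {path} (is an ffmpeg-capable imageio "
            f"plugin installed?): {exc}"
        ) from exc
    fps = meta.get("fps")
    return arr, float(fps) if fps else None


def load_stack(
    path: str | Path,
    frame_interval: float | None = None,
    roi: RegionOfInterest | None = None,
    frame_range: tuple[int, int] | None = None,
) -> ImageStack:
    """Load a recording from disk into an :class:`ImageStack`.

    Parameters
    ----------
    path
        Multi-page TIFF, a directory of numbered image files (natural
        sort order), or an AVI/MP4 container.
    frame_interval
        Seconds per frame.  Required unless the container carries a frame
        rate; an explicit value overrides container metadata.
    roi
        Optional rectangular crop applied after loading.
    frame_range
        Optional inclusive ``(first, last)`` frame indices to keep.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file or directory: {path}")

    meta_interval: float | None = None
    suffix = path.suffix.lower()
    if path.is_dir():
        arr = _read_directory(path)
    elif suffix in (".tif", ".tiff"):
        arr = _read_tiff(path)
    elif suffix in (".avi", ".mp4", ".mov"):
        arr, fps = _read_video(path)
        if fps:
            meta_interval = 1.0 / fps
    else:
        raise InputFormatError(
            f"unsupported input format {suffix!r}; expected TIFF stack, "
            "image directory, or AVI/MP4"
        )

    if suffix in LOSSY_SUFFIXES:
        logger.warning(
            "%s is a lossy-compressed format; compression artifacts inflate "
            "frame differences. Prefer uncompressed recordings.",
            path,
        )

    interval = frame_interval if frame_interval is not None else meta_interval
    if interval is None:
        raise MissingMetadataError(
            f"{path} carries no frame rate; pass frame_interval explicitly"
        )

    bit_depth = _bit_depth_of(arr)
    frames = to_grayscale(arr).astype(np.float64)

    if frame_range is not None:
        first, last = frame_range
        if not (0 <= first <= last < frames.shape[0]):
            raise BoundsError(
                f"frame_range {frame_range} outside [0, {frames.shape[0] - 1}]"
            )
        frames = frames[first : last + 1]
    if frames.shape[0] < 2:
        raise InsufficientDataError(
            "fewer than 2 frames after subsetting; cannot difference"
        )

    stack = ImageStack(
        frames=frames,
        frame_interval=float(interval),
        source_path=str(path),
        bit_depth_origin=bit_depth,
    )
    if roi is not None:
        stack = stack.crop(roi)
    return stack


def _fmt(x: float) -> str:
    return f"{x:.8g}"


def _write_trace_file(path: Path, trace: "MotionTrace", value_header: str) -> None:
    lines = [f"time_s\t{value_header}"]
    for t, v in zip(trace.times, trace.values):
        lines.append(f"{_fmt(t)}\t{_fmt(v)}")
    path.write_text("\n".join(lines) + "\n")


def read_trace_file(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a two-column trace file written by :func:`write_results`."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return data[:, 0], data[:, 1]


def write_results(
    contraction: "MotionTrace",
    velocity: "MotionTrace",
    beats: Sequence["BeatParameters"],
    out_dir: str | Path,
    make_plots: bool = False,
    log_entries: Mapping[str, object] | None = None,
    aligned_beats: Sequence[np.ndarray] | None = None,
) -> dict[str, Path]:
    """Write the standard result files for one recording.

    Always writes ``contraction.txt``, ``speed-of-contraction.txt`` and
    ``overview-results.txt`` (tab-separated, one header line) and appends a
    plain-text run log.  With ``make_plots`` also writes three PNGs: the
    contraction trace, the velocity trace, and the onset-aligned overlay of
    individual beats.
    """
    from .errors import CardiomotionError

    if len(contraction.values) != len(velocity.values):
        raise CardiomotionError(
            "contraction and velocity traces differ in length "
            f"({len(contraction.values)} vs {len(velocity.values)})"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    p = out_dir / RESULT_CONTRACTION
    _write_trace_file(p, contraction, "contraction_au")
    written["contraction"] = p

    p = out_dir / RESULT_VELOCITY
    _write_trace_file(p, velocity, "speed_of_contraction_au")
    written["velocity"] = p

    p = out_dir / RESULT_OVERVIEW
    lines = ["\t".join(OVERVIEW_COLUMNS)]
    for i, b in enumerate(beats):
        rr = "" if b.rr_interval is None else _fmt(b.rr_interval)
        lines.append(
            "\t".join(
                [
                    str(i),
                    _fmt(b.peak_time),
                    _fmt(b.amplitude),
                    _fmt(b.time_to_peak),
                    _fmt(b.relaxation_time),
                    _fmt(b.contraction_duration),
                    rr,
                ]
            )
        )
    p.write_text("\n".join(lines) + "\n")
    written["overview"] = p

    log_path = out_dir / RESULT_LOG
    log_lines = [f"n_frames\t{len(contraction.values)}", f"n_beats\t{len(beats)}"]
    for key, val in (log_entries or {}).items():
        log_lines.append(f"{key}\t{val}")
    with log_path.open("a") as fh:
        fh.write("\n".join(log_lines) + "\n")
    written["log"] = log_path

    if make_plots:
        written.update(
            _write_plots(contraction, velocity, aligned_beats or [], out_dir)
        )
    return written


def _write_plots(
    contraction: "MotionTrace",
    velocity: "MotionTrace",
    aligned: Sequence[np.ndarray],
    out_dir: Path,
) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out: dict[str, Path] = {}
    for name, trace, label in (
        ("contraction-trace.png", contraction, "contraction (a.u.)"),
        ("speed-of-contraction-trace.png", velocity, "speed of contraction (a.u.)"),
    ):
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(trace.times, trace.values, lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(label)
        fig.tight_layout()
        path = out_dir / name
        fig.savefig(path, dpi=100)
        plt.close(fig)
        out[name] = path

    fig, ax = plt.subplots(figsize=(4, 3))
    dt = contraction.frame_interval
    for seg in aligned:
        ax.plot(np.arange(len(seg)) * dt, seg, lw=0.8, alpha=0.7)
    ax.set_xlabel("time from onset (s)")
    ax.set_ylabel("contraction (a.u.)")
    fig.tight_layout()
    path = out_dir / "aligned-beats.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    out["aligned-beats.png"] = path
    return out
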