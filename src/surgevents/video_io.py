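"""Video reading/writing, stereo cropping, segment cutting and stream sync.

Console recordings arrive as side-by-side stereo files (both endoscope
oculars tiled horizontally); downstream analysis works on a single ocular,
so the first processing step is a vertical split. Recordings from different
devices (console capture vs. the motion camera filming the surgeon) start
at different wall-clock times; a shared physical marker — a clap visible in
both streams — gives one frame index per stream from which a clock offset
is derived and applied to event/label timestamps.

Two container families are supported:

* multi-page TIFF (``.tif``/``.tiff``) — lossless, self-contained, used for
  fixtures and intermediate files; frames-per-second is stored in the TIFF
  metadata.
* MP4/AVI via imageio's ffmpeg plugin, when that plugin is installed.

All in-memory video is a ``uint8`` array of shape ``(n_frames, h, w, 3)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .exceptions import GeometryError, ParameterError, VideoIOError

__all__ = [
    "VideoMeta",
    "SyncOffset",
    "read_video",
    "write_video",
    "probe",
    "split_stereo",
    "crop_stereo",
    "cut_segments",
    "find_offset",
    "apply_offset",
    "shift_times",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass(frozen=True)
class VideoMeta:
    """Container-level facts about a video file."""

    path: str
    width: int
    height: int
    fps: float
    n_frames: int

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class SyncOffset:
    """Clock offset between two streams sharing a physical marker.

    ``offset_s`` is the marker time in stream A minus the marker time in
    stream B; positive means A's marker occurs later on A's own clock.
    """

    offset_s: float

    def inverse(self) -> "SyncOffset":
        return SyncOffset(-self.offset_s)


def _as_rgb_stack(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 3:  # grayscale stack -> replicate channels
        frames = np.repeat(frames[..., None], 3, axis=3)
    if frames.ndim != 4 or frames.shape[3] != 3:
        raise VideoIOError(
            f"expected frames of shape (n, h, w, 3), got {frames.shape}"
        )
    return np.ascontiguousarray(frames.astype(np.uint8, copy=False))


def write_video(path: str | Path, frames: np.ndarray, fps: float) -> VideoMeta:
    """Write a frame stack to *path*; format chosen by file suffix."""
    if fps <= 0:
        raise ParameterError(f"fps must be positive, got {fps}")
    frames = _as_rgb_stack(frames)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(
            path,
            frames,
            photometric="rgb",
            description=json.dumps({"fps": float(fps)}),
        )
    else:
        _write_video_ffmpeg(path, frames, fps)
    n, h, w, _ = frames.shape
    return VideoMeta(str(path), width=w, height=h, fps=float(fps), n_frames=n)


def _write_video_ffmpeg(path: Path, frames: np.ndarray, fps: float) -> None:
    try:
        import imageio.v3 as iio

        iio.imwrite(path, frames, fps=fps, plugin="FFMPEG")
    except ImportError as exc:  # pragma: no cover - depends on optional plugin
        raise VideoIOError(
            f"writing {path.suffix} requires imageio's ffmpeg plugin "
            "(pip install imageio-ffmpeg); lossless .tif output needs no plugin"
        ) from exc


def read_video(path: str | Path, fps: float | None = None) -> tuple[np.ndarray, float]:
    """Read a video file into ``(frames, fps)``.

    ``fps`` overrides whatever the container metadata reports; recordings in
    the wild mix 15 and 30 FPS and container metadata is not always trusted.
    """
    path = Path(path)
    if not path.exists():
        raise VideoIOError(f"video file not found: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        frames, meta_fps = _read_tiff(path)
    else:
        frames, meta_fps = _read_ffmpeg(path)
    return frames, float(fps if fps is not None else meta_fps)


def _read_tiff(path: Path) -> tuple[np.ndarray, float]:
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            desc = tif.pages[0].description or ""
    except Exception as exc:
        raise VideoIOError(f"could not read TIFF video {path}: {exc}") from exc
    fps = 1.0
    try:
        fps = float(json.loads(desc).get("fps", 1.0))
    except (json.JSONDecodeError, AttributeError, TypeError):
        pass
    if frames.ndim == 3 and frames.shape[-1] == 3:  # single frame
        frames = frames[None]
    return _as_rgb_stack(frames), fps


def _read_ffmpeg(path: Path) -> tuple[np.ndarray, float]:
    try:
        import imageio.v3 as iio

        frames = iio.imread(path, plugin="FFMPEG")
        meta = iio.immeta(path, plugin="FFMPEG")
        return _as_rgb_stack(frames), float(meta.get("fps", 1.0))
    except ImportError as exc:
        raise VideoIOError(
            f"reading {path.suffix} requires imageio's ffmpeg plugin "
            "(pip install imageio-ffmpeg)"
        ) from exc
    except Exception as exc:
        raise VideoIOError(f"could not read video {path}: {exc}") from exc


def probe(path: str | Path, fps: float | None = None) -> VideoMeta:
    """Return :class:`VideoMeta` for a file (reads it fully; files are short)."""
    frames, file_fps = read_video(path, fps=fps)
    n, h, w, _ = frames.shape
    return VideoMeta(str(path), width=w, height=h, fps=file_fps, n_frames=n)


# ---------------------------------------------------------------------------
# stereo crop
# ---------------------------------------------------------------------------

def split_stereo(frames: np.ndarray, side: str) -> np.ndarray:
    """Return the left or right half of a side-by-side stereo frame stack.

    Left is columns ``[0, w/2)``, right is ``[w/2, w)``; height and frame
    count are unchanged.
    """
    frames = _as_rgb_stack(frames)
    w = frames.shape[2]
    if w % 2 != 0:
        raise GeometryError(f"stereo frame width must be even, got {w}")
    half = w // 2
    if side == "left":
        return frames[:, :, :half, :].copy()
    if side == "right":
        return frames[:, :, half:, :].copy()
    raise ParameterError(f"side must be 'left' or 'right', got {side!r}")


def crop_stereo(video: str | Path, side: str, out: str | Path,
                fps: float | None = None) -> VideoMeta:
    """File-level stereo crop: read *video*, keep one ocular, write *out*."""
    frames, file_fps = read_video(video, fps=fps)
    return write_video(out, split_stereo(frames, side), file_fps)


# ---------------------------------------------------------------------------
# segment cutting
# ---------------------------------------------------------------------------

def cut_segments(video: str | Path, keep: Sequence[tuple[float, float]],
                 out: str | Path, fps: float | None = None) -> VideoMeta:
    """Concatenate the kept time intervals of *video* into *out*.

    ``keep`` is a sorted list of non-overlapping ``(start_s, end_s)``
    half-open intervals; frame ranges are ``[round(start*fps),
    round(end*fps))``. Refuses to emit an empty video.
    """
    if not keep:
        raise ParameterError("keep list is empty; refusing to emit an empty video")
    frames, file_fps = read_video(video, fps=fps)
    n = frames.shape[0]
    prev_end = -np.inf
    pieces = []
    for start_s, end_s in keep:
        if end_s <= start_s:
            raise ParameterError(f"interval ({start_s}, {end_s}) is empty or reversed")
        if start_s < prev_end:
            raise ParameterError(
                f"keep intervals overlap or are unsorted near ({start_s}, {end_s})"
            )
        prev_end = end_s
        f0 = int(round(start_s * file_fps))
        f1 = int(round(end_s * file_fps))
        if f0 < 0 or f1 > n:
            raise ParameterError(
                f"interval ({start_s}, {end_s}) s exceeds video duration "
                f"({n / file_fps:.3f} s)"
            )
        pieces.append(frames[f0:f1])
    return write_video(out, np.concatenate(pieces, axis=0), file_fps)


# ---------------------------------------------------------------------------
# two-stream synchronization
# ---------------------------------------------------------------------------

def find_offset(marker_frame_a: int, fps_a: float,
                marker_frame_b: int, fps_b: float) -> SyncOffset:
    """Offset between two streams from the marker frame seen in each.

    The marker is one physical instant (e.g. a clap) visible in both
    streams; ``offset_s = marker_frame_a/fps_a - marker_frame_b/fps_b``.
    """
    if marker_frame_a < 0 or marker_frame_b < 0:
        raise ParameterError("marker frame indices must be non-negative")
    if fps_a <= 0 or fps_b <= 0:
        raise ParameterError("fps must be positive for both streams")
    return SyncOffset(marker_frame_a / fps_a - marker_frame_b / fps_b)


def shift_times(times_s: Sequence[float], offset: SyncOffset,
                ) -> tuple[list[float], list[bool]]:
    """Shift timestamps by ``-offset_s`` onto the reference stream's clock.

    Returns the shifted times and a per-record flag marking values that had
    to be clamped to zero (a shift would otherwise produce negative time).
    """
    shifted, clamped = [], []
    for t in times_s:
        s = t - offset.offset_s
        if s < 0:
            warnings.warn(
                f"timestamp {t:.3f}s shifted to {s:.3f}s; clamped to 0",
                stacklevel=2,
            )
            shifted.append(0.0)
            clamped.append(True)
        else:
            shifted.append(s)
            clamped.append(False)
    return shifted, clamped


def apply_offset(records, offset: SyncOffset):
    """Shift the timestamps of events or labels onto a common clock.

    Accepts a sequence of floats (returned as a new list), or any sequence
    of objects exposing ``time_s`` or ``start_s`` (returned as shifted
    copies via ``dataclasses.replace``). Ordering is preserved.
    """
    import dataclasses

    records = list(records)
    if not records:
        return []
    if isinstance(records[0], (int, float)):
        shifted, _ = shift_times([float(t) for t in records], offset)
        return shifted

    out = []
    for rec in records:
        if hasattr(rec, "time_s"):
            (t,), _ = shift_times([rec.time_s], offset)
            out.append(dataclasses.replace(rec, time_s=t))
        elif hasattr(rec, "start_s"):
            (t,), _ = shift_times([rec.start_s], offset)
            out.append(dataclasses.replace(rec, start_s=t))
        else:
            raise ParameterError(
                f"record {rec!r} carries no time_s/start_s timestamp"
            )
    return out
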