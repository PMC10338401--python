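"""Synthetic console recordings and fixtures with exact ground truth.

Real console overlays are proprietary imagery, and the detection method
needs only geometric and photometric fidelity to its *own* profile: a
template matcher that recovers scripted events from frames it rendered
itself exercises exactly the same code path as one fed capture-card
footage. This module therefore renders console videos from scripted event
timelines — each scripted activation paints the channel's indicator
template into its ROI over a pseudo-random background — and emits the
ground-truth event log alongside. The same renderer's ROI crops *are* the
profile's templates, so profile and footage are self-consistent by
construction.

Ground truth for the other modules comes from the same philosophy:
landmark streams are generated with their true path length computed at
generation time, and annotation TSV files are packed from requested
per-subcategory counts.

Everything is deterministic per seed: identical seeds give byte-identical
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import CountTable, LabelEvent, LabelSchema, default_schema, serialize_labels
from .event_detection import EventLog, EventRecord
from .exceptions import PackingError, ParameterError, ValidationError
from .profiles import (
    GENERATION_CHANNELS,
    EventChannel,
    Generation,
    IndicatorSpec,
    ROISpec,
    SystemProfile,
)

__all__ = [
    "TimelineSpan",
    "EventTimeline",
    "SyntheticScene",
    "build_toy_profile",
    "generate_console_video",
    "random_timeline",
    "adapt_timeline",
    "generate_landmark_stream",
    "generate_label_file",
    "MAX_EXACT_NOISE_SIGMA",
]

#: Largest Gaussian pixel-noise standard deviation (8-bit scale) at which
#: event recovery on toy-profile renders stays exact. The stripe templates
#: have per-pixel SD ~= 60, so noise of sigma 8 leaves the normalized
#: correlation near 1/sqrt(1 + (8/60)^2) ~= 0.99, comfortably above the
#: 0.95 threshold, while background crops stay near 0.
MAX_EXACT_NOISE_SIGMA = 8.0


@dataclass(frozen=True)
class TimelineSpan:
    """One scripted indicator span, half-open in seconds."""

    channel: EventChannel
    start_s: float
    end_s: float
    state: str = "active"  # "active" | "hover"

    def __post_init__(self):
        object.__setattr__(self, "channel", EventChannel(self.channel))
        if self.end_s <= self.start_s:
            raise ValidationError(
                f"span for {self.channel.value} must have end > start, "
                f"got [{self.start_s}, {self.end_s})"
            )
        if self.state not in ("active", "hover"):
            raise ValidationError(f"span state must be active|hover, got {self.state!r}")

    def frames(self, fps: float) -> tuple[int, int]:
        return int(round(self.start_s * fps)), int(round(self.end_s * fps))


@dataclass
class EventTimeline:
    """Scripted ground truth: which indicator is lit when."""

    spans: list[TimelineSpan]
    fps: float
    duration_s: float
    resolution: tuple[int, int]  # (width, height)

    def __post_init__(self):
        self.spans = [s if isinstance(s, TimelineSpan) else TimelineSpan(**s)
                      for s in self.spans]
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValidationError("fps and duration must be positive")
        per_channel: dict[EventChannel, list[TimelineSpan]] = {}
        for span in self.spans:
            if span.end_s > self.duration_s or span.start_s < 0:
                raise ValidationError(
                    f"span {span} lies outside [0, {self.duration_s}) s"
                )
            per_channel.setdefault(span.channel, []).append(span)
        for channel, spans in per_channel.items():
            spans = sorted(spans, key=lambda s: s.start_s)
            for a, b in zip(spans, spans[1:]):
                if b.start_s < a.end_s:
                    raise ValidationError(
                        f"overlapping spans for {channel.value}: {a} / {b}"
                    )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def active_spans(self) -> list[TimelineSpan]:
        return [s for s in self.spans if s.state == "active"]

    def scripted_counts(self) -> dict[EventChannel, int]:
        counts: dict[EventChannel, int] = {}
        for span in self.active_spans():
            counts[span.channel] = counts.get(span.channel, 0) + 1
        return counts

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "fps": self.fps,
            "duration_s": self.duration_s,
            "resolution": list(self.resolution),
            "spans": [{
                "channel": s.channel.value, "start_s": s.start_s,
                "end_s": s.end_s, "state": s.state,
            } for s in self.spans],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EventTimeline":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            spans=[TimelineSpan(
                channel=EventChannel(s["channel"]), start_s=float(s["start_s"]),
                end_s=float(s["end_s"]), state=s.get("state", "active"),
            ) for s in raw["spans"]],
            fps=float(raw["fps"]),
            duration_s=float(raw["duration_s"]),
            resolution=tuple(raw["resolution"]),
        )


@dataclass(frozen=True)
class SyntheticScene:
    """Rendering knobs: background texture, pixel noise, seed."""

    noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_amplitude < 0:
            raise ValidationError("noise amplitude must be >= 0")


# ---------------------------------------------------------------------------
# toy profiles
# ---------------------------------------------------------------------------

_PALETTE = [
    ((40, 160, 215), (200, 60, 40)),
    ((215, 180, 40), (40, 60, 200)),
    ((60, 200, 120), (180, 40, 180)),
    ((200, 200, 60), (60, 80, 160)),
    ((215, 90, 40), (40, 190, 190)),
    ((120, 60, 200), (190, 190, 60)),
    ((40, 120, 200), (200, 140, 60)),
    ((180, 60, 60), (60, 180, 90)),
]


def _render_indicator(channel_index: int, state: str, h: int, w: int) -> np.ndarray:
    """Deterministic striped glyph for one indicator state.

    Active templates use diagonal stripes of a per-channel color pair;
    hover templates use anti-diagonal stripes of a green pair, so hover and
    active crops of the same ROI decorrelate.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    period = 3 + channel_index % 4
    if state == "active":
        c1, c2 = _PALETTE[channel_index % len(_PALETTE)]
        mask = ((xx + yy) // period) % 2 == 0
    else:
        c1, c2 = (60, 190, 80), (110, 230, 150)
        mask = ((xx - yy) // (period + 1)) % 2 == 0
    img = np.where(mask[..., None], np.array(c1, np.uint8), np.array(c2, np.uint8))
    return img.astype(np.uint8)


def build_toy_profile(generation: Generation | str,
                      frame_size: tuple[int, int] = (320, 180),
                      fps: float = 15.0) -> SystemProfile:
    """Small deterministic profile whose templates the renderer reproduces.

    Indicators are laid out in a row along the bottom of the frame (the
    console places its panels there too); the Si variant shifts the row up
    a few pixels so the two generations genuinely differ in geometry.
    """
    generation = Generation(generation)
    width, height = frame_size
    channels = sorted(GENERATION_CHANNELS[generation], key=lambda c: c.value)
    box_w, box_h, margin = 28, 22, 8
    y = height - box_h - (margin if generation is Generation.XI else 2 * margin)
    indicators = []
    for i, channel in enumerate(channels):
        x = margin + i * (box_w + margin)
        if x + box_w > width:
            raise ValidationError(
                f"frame width {width} too small for {len(channels)} indicators"
            )
        indicators.append(IndicatorSpec(
            channel=channel,
            roi=ROISpec(x=x, y=y, w=box_w, h=box_h),
            active_template=_render_indicator(i, "active", box_h, box_w),
            hover_template=_render_indicator(i, "hover", box_h, box_w),
        ))
    return SystemProfile(
        generation=generation, frame_width=width, frame_height=height,
        indicators=indicators, fps_default=fps,
    )


# ---------------------------------------------------------------------------
# console video rendering
# ---------------------------------------------------------------------------

def generate_console_video(timeline: EventTimeline, profile: SystemProfile,
                           scene: SyntheticScene | None = None,
                           out_path: str | Path | None = None,
                           ) -> tuple[np.ndarray, EventLog]:
    """Render a timeline into frames plus its ground-truth event log.

    Each scripted active span paints the channel's active template into its
    ROI for frames ``[round(start_s*fps), round(end_s*fps))``; hover spans
    paint the hover template. The background is a per-video pseudo-random
    texture (fixed across frames), optionally overlaid with per-frame
    Gaussian pixel noise of the scene's amplitude.
    """
    if scene is None:
        scene = SyntheticScene()
    w, h = timeline.resolution
    if (w, h) != (profile.frame_width, profile.frame_height):
        raise ValidationError(
            f"timeline resolution {w}x{h} differs from profile "
            f"{profile.frame_width}x{profile.frame_height}"
        )
    profile_channels = set(profile.channels)
    for span in timeline.spans:
        if span.channel not in profile_channels:
            raise ValidationError(
                f"timeline channel {span.channel.value} has no indicator in "
                f"the {profile.generation.value} profile"
            )

    rng = np.random.default_rng(scene.seed)
    background = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    n_frames = timeline.n_frames
    frames = np.broadcast_to(background, (n_frames, h, w, 3)).copy()

    truth_events = []
    for span in timeline.spans:
        f0, f1 = span.frames(timeline.fps)
        spec = profile.indicator(span.channel)
        template = (spec.active_template if span.state == "active"
                    else spec.hover_template)
        roi = spec.roi
        frames[f0:f1, roi.y:roi.y + roi.h, roi.x:roi.x + roi.w] = template
        if span.state == "active":
            truth_events.append(EventRecord(
                channel=span.channel, start_frame=f0, end_frame=f1,
                start_s=f0 / timeline.fps,
                duration_s=(f1 - f0) / timeline.fps,
            ))

    if scene.noise_amplitude > 0:
        noise = rng.normal(0.0, scene.noise_amplitude, size=frames.shape)
        frames = np.clip(frames.astype(np.float64) + noise, 0, 255)
        frames = frames.astype(np.uint8)

    truth = EventLog(
        video_id=(Path(out_path).stem if out_path else "synthetic"),
        fps=timeline.fps, n_frames=n_frames, events=truth_events,
    )
    if out_path is not None:
        from .video_io import write_video

        write_video(out_path, frames, timeline.fps)
    return frames, truth


def random_timeline(profile: SystemProfile, duration_s: float = 20.0,
                    seed: int = 0, max_events_per_channel: int = 3,
                    hover_prob: float = 0.4,
                    channels: Optional[Sequence[EventChannel]] = None,
                    ) -> EventTimeline:
    """Seeded random timeline of non-overlapping spans per channel.

    Spans are generated on the frame grid with at least two inactive frames
    between consecutive spans of a channel, so every scripted span maps to
    exactly one maximal active run in the render. Optionally a hover span
    directly precedes an active one (foot settling above the pedal before
    the press).
    """
    rng = np.random.default_rng(seed)
    fps = profile.fps_default
    n_frames = int(round(duration_s * fps))
    if channels is None:
        channels = profile.channels
    spans: list[TimelineSpan] = []
    for channel in channels:
        n_events = int(rng.integers(0, max_events_per_channel + 1))
        cursor = int(rng.integers(0, 6))
        for _ in range(n_events):
            length = int(rng.integers(2, 9))
            hover_len = int(rng.integers(1, 4)) if rng.random() < hover_prob else 0
            if cursor + hover_len + length >= n_frames:
                break
            if hover_len:
                spans.append(TimelineSpan(
                    channel=channel, start_s=cursor / fps,
                    end_s=(cursor + hover_len) / fps, state="hover",
                ))
            f0 = cursor + hover_len
            spans.append(TimelineSpan(
                channel=channel, start_s=f0 / fps,
                end_s=(f0 + length) / fps, state="active",
            ))
            cursor = f0 + length + 2 + int(rng.integers(0, 12))
    return EventTimeline(
        spans=spans, fps=fps, duration_s=n_frames / fps,
        resolution=(profile.frame_width, profile.frame_height),
    )


def adapt_timeline(timeline: EventTimeline, profile: SystemProfile,
                   ) -> EventTimeline:
    """Map a generation-neutral timeline onto a profile's channel set.

    The conjoined ``CLUTCH`` channel maps to ``CLUTCH_L`` on per-arm
    consoles; per-arm clutches both map back to ``CLUTCH`` on conjoined
    ones (which fails validation if the scripted spans then overlap —
    a genuinely ambiguous timeline).
    """
    mapping = {
        Generation.XI: {EventChannel.CLUTCH: EventChannel.CLUTCH_L},
        Generation.SI: {EventChannel.CLUTCH_L: EventChannel.CLUTCH,
                        EventChannel.CLUTCH_R: EventChannel.CLUTCH},
    }[profile.generation]
    spans = [TimelineSpan(
        channel=mapping.get(s.channel, s.channel),
        start_s=s.start_s, end_s=s.end_s, state=s.state,
    ) for s in timeline.spans]
    return EventTimeline(
        spans=spans, fps=timeline.fps, duration_s=timeline.duration_s,
        resolution=(profile.frame_width, profile.frame_height),
    )


# ---------------------------------------------------------------------------
# landmark streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkStreamTruth:
    """Analytic ground truth for a generated landmark stream."""

    path_length_px: float  # bridge-policy length over the emitted points
    n_points: int


def generate_landmark_stream(n_steps: int = 500, seed: int = 0,
                             waypoints: Optional[Sequence[tuple[float, float]]] = None,
                             frame_size: tuple[int, int] = (320, 180),
                             step_sigma: float = 3.0,
                             dropout: float = 0.0,
                             hand: str = "right", landmark: str = "wrist",
                             fps: float = 15.0,
                             out_path: str | Path | None = None,
                             ) -> tuple[pd.DataFrame, LandmarkStreamTruth]:
    """Landmark stream with its true path length computed at generation.

    Either a seeded random walk of ``n_steps`` (reflected at the frame
    borders) or an explicit waypoint sequence. ``dropout`` removes each
    non-endpoint frame with that probability, creating tracking gaps; the
    truth is the bridge-policy length over the points actually emitted.
    """
    if not 0.0 <= dropout < 1.0:
        raise ParameterError(f"dropout must be in [0, 1), got {dropout}")
    rng = np.random.default_rng(seed)
    w, h = frame_size
    if waypoints is not None:
        pts = np.asarray(waypoints, dtype=np.float64).reshape(-1, 2)
    else:
        steps = rng.normal(0.0, step_sigma, size=(n_steps, 2))
        pts = np.empty((n_steps + 1, 2))
        pts[0] = (w / 2.0, h / 2.0)
        np.cumsum(steps, axis=0, out=steps)
        pts[1:] = pts[0] + steps
        # reflect into the frame so every observation stays valid
        pts[:, 0] = np.abs(np.mod(pts[:, 0], 2 * (w - 1)))
        pts[:, 0] = np.where(pts[:, 0] > w - 1, 2 * (w - 1) - pts[:, 0], pts[:, 0])
        pts[:, 1] = np.abs(np.mod(pts[:, 1], 2 * (h - 1)))
        pts[:, 1] = np.where(pts[:, 1] > h - 1, 2 * (h - 1) - pts[:, 1], pts[:, 1])

    frames = np.arange(len(pts))
    if dropout > 0 and len(pts) > 2:
        keep = rng.random(len(pts)) >= dropout
        keep[0] = keep[-1] = True  # endpoints anchor the track
        pts, frames = pts[keep], frames[keep]

    true_length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    df = pd.DataFrame({
        "frame_index": frames,
        "hand": hand,
        "landmark": landmark,
        "x": pts[:, 0],
        "y": pts[:, 1],
        "confidence": 1.0,
    })
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df, LandmarkStreamTruth(true_length, len(pts))


# ---------------------------------------------------------------------------
# label files
# ---------------------------------------------------------------------------

def generate_label_file(counts: dict[str, int], duration_s: float,
                        schema: LabelSchema | None = None, seed: int = 0,
                        out_path: str | Path | None = None,
                        min_interval_s: float = 1e-3,
                        ) -> tuple[list[LabelEvent], CountTable]:
    """Pack requested per-subcategory interval counts into a label file.

    Intervals are laid out on an even grid over the duration and shuffled
    across behaviors, producing a well-formed START/STOP stream whose
    aggregation returns exactly the requested counts.
    """
    if schema is None:
        schema = default_schema()
    for behavior, n in counts.items():
        if behavior not in schema:
            raise ParameterError(f"behavior {behavior!r} is not in the schema")
        if n < 0:
            raise ParameterError(f"count for {behavior!r} must be >= 0")
    total = sum(counts.values())
    truth = CountTable(schema=schema, subcategory_counts=dict(counts))
    if total == 0:
        if out_path is not None:
            serialize_labels([], out_path)
        return [], truth
    if duration_s <= 0:
        raise PackingError("duration must be positive")
    slot = duration_s / total
    if slot <= min_interval_s:
        raise PackingError(
            f"{total} intervals of >= {min_interval_s}s do not fit into "
            f"{duration_s}s"
        )
    rng = np.random.default_rng(seed)
    behaviors = [b for b, n in sorted(counts.items()) for _ in range(n)]
    rng.shuffle(behaviors)
    events: list[LabelEvent] = []
    for i, behavior in enumerate(behaviors):
        start = i * slot
        stop = start + max(min_interval_s, 0.8 * slot)
        events.append(LabelEvent(time_s=start, behavior=behavior, status="START"))
        events.append(LabelEvent(time_s=stop, behavior=behavior, status="STOP"))
    events.sort(key=lambda e: e.time_s)
    if out_path is not None:
        serialize_labels(events, out_path)
    return events, truth
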