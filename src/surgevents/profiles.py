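"""System profiles: which on-screen indicators exist and where they live.

A *profile* describes one robot generation's console overlay: for every
event channel (cut/coagulation pedals, clutch, third-arm swap, camera) it
records the rectangle of the screen where the indicator appears, the
template image of the indicator's pressed ("active") state, optionally a
template of the foot-hover state, and the correlation threshold above which
the template is considered matched.

The two supported generations differ in clutch semantics: the Si console
only clutches both hand controllers together, so an Si profile exposes one
``CLUTCH`` channel; the Xi clutches per arm and exposes ``CLUTCH_L`` /
``CLUTCH_R``. The indicators' on-screen placement also differs between
generations, which is exactly why the geometry is configuration rather
than code: a profile is a calibration artifact (YAML + PNG templates)
shipped per installation.

Pixel conventions, used everywhere in this package: 0-based coordinates,
origin at the top-left, rectangles half-open ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .exceptions import ProfileError, ValidationError

__all__ = [
    "EventChannel",
    "Generation",
    "ROISpec",
    "IndicatorSpec",
    "SystemProfile",
    "DEFAULT_THRESHOLDS",
    "default_threshold",
    "load_profile",
    "save_profile",
    "validate_templates",
]


class EventChannel(str, enum.Enum):
    """Discrete console functions whose activation is detectable on screen."""

    CUT_L = "CUT_L"
    CUT_R = "CUT_R"
    COAG_L = "COAG_L"
    COAG_R = "COAG_R"
    CLUTCH = "CLUTCH"        # Si: conjoined clutch for both controllers
    CLUTCH_L = "CLUTCH_L"    # Xi: per-arm clutch
    CLUTCH_R = "CLUTCH_R"
    THIRD_ARM_SWAP = "THIRD_ARM_SWAP"
    CAMERA = "CAMERA"

    @property
    def side(self) -> str:
        """Which side of the picture the indicator refers to."""
        if self.name.endswith("_L"):
            return "left"
        if self.name.endswith("_R"):
            return "right"
        return "none"


class Generation(str, enum.Enum):
    SI = "SI"
    XI = "XI"


#: Channels a profile of each generation may declare.
GENERATION_CHANNELS = {
    Generation.SI: frozenset({
        EventChannel.CUT_L, EventChannel.CUT_R,
        EventChannel.COAG_L, EventChannel.COAG_R,
        EventChannel.CLUTCH,
        EventChannel.THIRD_ARM_SWAP, EventChannel.CAMERA,
    }),
    Generation.XI: frozenset({
        EventChannel.CUT_L, EventChannel.CUT_R,
        EventChannel.COAG_L, EventChannel.COAG_R,
        EventChannel.CLUTCH_L, EventChannel.CLUTCH_R,
        EventChannel.THIRD_ARM_SWAP, EventChannel.CAMERA,
    }),
}

#: Default match thresholds: 0.95 for the energy pedals and clutch, 0.90
#: for camera movement and third-arm swap. Cut inherits the coagulation
#: value: both are pedal indicators with the same on-screen footprint.
DEFAULT_THRESHOLDS = {
    EventChannel.CUT_L: 0.95,
    EventChannel.CUT_R: 0.95,
    EventChannel.COAG_L: 0.95,
    EventChannel.COAG_R: 0.95,
    EventChannel.CLUTCH: 0.95,
    EventChannel.CLUTCH_L: 0.95,
    EventChannel.CLUTCH_R: 0.95,
    EventChannel.THIRD_ARM_SWAP: 0.90,
    EventChannel.CAMERA: 0.90,
}


def default_threshold(channel: EventChannel) -> float:
    return DEFAULT_THRESHOLDS[channel]


@dataclass(frozen=True)
class ROISpec:
    """Half-open pixel rectangle ``[x, x+w) x [y, y+h)``, top-left origin."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise ValidationError(f"ROI origin must be non-negative, got {self}")
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"ROI extent must be positive, got {self}")

    def fits_in(self, frame_width: int, frame_height: int) -> bool:
        return self.x + self.w <= frame_width and self.y + self.h <= frame_height

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.y:self.y + self.h, self.x:self.x + self.w]


@dataclass
class IndicatorSpec:
    """One detectable indicator: where it is and what it looks like."""

    channel: EventChannel
    roi: ROISpec
    active_template: np.ndarray
    hover_template: Optional[np.ndarray] = None
    threshold: Optional[float] = None  # None -> channel default

    def __post_init__(self):
        self.channel = EventChannel(self.channel)
        if self.threshold is None:
            self.threshold = default_threshold(self.channel)
        if not 0.0 < self.threshold <= 1.0:
            raise ValidationError(
                f"{self.channel.value}: threshold must be in (0, 1], "
                f"got {self.threshold}"
            )
        self.active_template = np.asarray(self.active_template)
        if self.active_template.shape[:2] != (self.roi.h, self.roi.w):
            raise ValidationError(
                f"{self.channel.value}: active template shape "
                f"{self.active_template.shape[:2]} differs from ROI "
                f"({self.roi.h}, {self.roi.w})"
            )
        if self.hover_template is not None:
            self.hover_template = np.asarray(self.hover_template)
            if self.hover_template.shape[:2] != (self.roi.h, self.roi.w):
                raise ValidationError(
                    f"{self.channel.value}: hover template shape "
                    f"{self.hover_template.shape[:2]} differs from ROI "
                    f"({self.roi.h}, {self.roi.w})"
                )


@dataclass
class SystemProfile:
    """Per-generation description of all indicators of one console layout."""

    generation: Generation
    frame_width: int
    frame_height: int
    indicators: list[IndicatorSpec] = field(default_factory=list)
    fps_default: float = 15.0

    def __post_init__(self):
        self.generation = Generation(self.generation)
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValidationError("frame resolution must be positive")
        seen: set[EventChannel] = set()
        allowed = GENERATION_CHANNELS[self.generation]
        for spec in self.indicators:
            if spec.channel in seen:
                raise ValidationError(
                    f"duplicate indicator for channel {spec.channel.value}"
                )
            seen.add(spec.channel)
            if spec.channel not in allowed:
                raise ValidationError(
                    f"channel {spec.channel.value} is not valid for a "
                    f"{self.generation.value} profile"
                )
            if not spec.roi.fits_in(self.frame_width, self.frame_height):
                raise ValidationError(
                    f"{spec.channel.value}: ROI {spec.roi} exceeds frame "
                    f"{self.frame_width}x{self.frame_height}"
                )

    @property
    def channels(self) -> list[EventChannel]:
        return [spec.channel for spec in self.indicators]

    def indicator(self, channel: EventChannel) -> IndicatorSpec:
        for spec in self.indicators:
            if spec.channel == EventChannel(channel):
                return spec
        raise KeyError(f"profile has no indicator for {channel}")


# ---------------------------------------------------------------------------
# YAML + PNG (de)serialization
# ---------------------------------------------------------------------------

def _read_template(path: Path, channel: str) -> np.ndarray:
    if not path.exists():
        raise ProfileError(
            f"template image for channel {channel} not found: {path}"
        )
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    return img


def load_profile(config_path: str | Path) -> SystemProfile:
    """Load and validate a profile from YAML; template paths are relative
    to the YAML file's directory. Omitted thresholds take channel defaults."""
    config_path = Path(config_path)
    if not config_path.exists():
        raise ProfileError(f"profile config not found: {config_path}")
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ProfileError(f"profile config {config_path} is not a mapping")
    base = config_path.parent
    indicators = []
    for entry in raw.get("indicators", []):
        channel = entry["channel"]
        roi = ROISpec(**entry["roi"])
        active = _read_template(base / entry["active_template"], channel)
        hover = None
        if entry.get("hover_template"):
            hover = _read_template(base / entry["hover_template"], channel)
        indicators.append(IndicatorSpec(
            channel=EventChannel(channel),
            roi=roi,
            active_template=active,
            hover_template=hover,
            threshold=entry.get("threshold"),
        ))
    return SystemProfile(
        generation=Generation(raw["generation"]),
        frame_width=int(raw["frame_width"]),
        frame_height=int(raw["frame_height"]),
        indicators=indicators,
        fps_default=float(raw.get("fps_default", 15.0)),
    )


def save_profile(profile: SystemProfile, config_path: str | Path) -> Path:
    """Write a profile to YAML plus a sibling ``<stem>_templates/`` PNG dir."""
    import imageio.v3 as iio

    config_path = Path(config_path)
    config_path.parent.mkdir(parents=True, exist_ok=True)
    tpl_dir = config_path.parent / f"{config_path.stem}_templates"
    tpl_dir.mkdir(exist_ok=True)
    entries = []
    for spec in profile.indicators:
        name = spec.channel.value.lower()
        active_rel = f"{tpl_dir.name}/{name}_active.png"
        iio.imwrite(config_path.parent / active_rel,
                    np.asarray(spec.active_template, dtype=np.uint8))
        entry = {
            "channel": spec.channel.value,
            "roi": {"x": spec.roi.x, "y": spec.roi.y,
                    "w": spec.roi.w, "h": spec.roi.h},
            "active_template": active_rel,
            "threshold": float(spec.threshold),
        }
        if spec.hover_template is not None:
            hover_rel = f"{tpl_dir.name}/{name}_hover.png"
            iio.imwrite(config_path.parent / hover_rel,
                        np.asarray(spec.hover_template, dtype=np.uint8))
            entry["hover_template"] = hover_rel
        entries.append(entry)
    doc = {
        "generation": profile.generation.value,
        "frame_width": profile.frame_width,
        "frame_height": profile.frame_height,
        "fps_default": profile.fps_default,
        "indicators": entries,
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return config_path


# ---------------------------------------------------------------------------
# template/resolution validation
# ---------------------------------------------------------------------------

def validate_templates(profile: SystemProfile,
                       video_resolution: tuple[int, int]) -> list[dict]:
    """Check each indicator's geometry against a video's resolution.

    Template matching is resolution-bound: patterns recorded at one
    resolution simply never match frames at another, which silently yields
    zero events. This report makes the mismatch explicit; callers treat any
    MISMATCH entry as fatal before running detection.

    Returns a JSON-serializable list of ``{channel, status, detail}`` with
    status ``"OK"`` or ``"MISMATCH"``.
    """
    vid_w, vid_h = video_resolution
    report = []
    res_ok = (profile.frame_width, profile.frame_height) == (vid_w, vid_h)
    for spec in profile.indicators:
        if not res_ok:
            status, detail = "MISMATCH", (
                f"profile assumes {profile.frame_width}x{profile.frame_height}, "
                f"video is {vid_w}x{vid_h}"
            )
        elif not spec.roi.fits_in(vid_w, vid_h):
            status, detail = "MISMATCH", f"ROI {spec.roi} exceeds video frame"
        else:
            status, detail = "OK", ""
        report.append({
            "channel": spec.channel.value,
            "status": status,
            "detail": detail,
        })
    return report
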