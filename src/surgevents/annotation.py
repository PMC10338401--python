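"""Temporal annotations: behavioral-observation TSV parsing and aggregation.

Temporal labels mark when a surgical behavior starts and stops in a
recording. The de-facto exchange format is the tab-separated export of
behavioral-observation software (BORIS and kin): one row per state change
with *Time* (decimal seconds), *Behavior* (the subcategory name) and
*Status* (START or STOP) columns, plus assorted extra columns that are
ignored here. Each START is paired with the next STOP of the same behavior
to form an interval; intervals of different behaviors freely interleave and
nest (a suture can be handled while the camera is being moved).

Behaviors are organized in a two-level schema — category -> subcategories —
so counts can be analyzed per fine-grained behavior or rolled up. The
bundled default schema covers the three basic elements of surgery:
suturing, dissection, and a catch-all "other" (suction, holding, camera
handling, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .exceptions import PairingError, ParameterError, ParseError, ValidationError

__all__ = [
    "LabelSchema",
    "LabelEvent",
    "LabelInterval",
    "CountTable",
    "default_schema",
    "parse_labels",
    "serialize_labels",
    "build_intervals",
    "extract_clips",
    "aggregate_label_counts",
]

#: Default annotation schema: the three basic elements of surgery with the
#: subcategories used for intraabdominal robot-assisted procedures.
DEFAULT_SCHEMA_CATEGORIES: dict[str, list[str]] = {
    "suturing": [
        "Suture puncture",
        "Suture handling",
        "Suture, single",
        "Suture, running",
    ],
    "dissection": [
        "Dissection, ordinary",
        "Dissection, clips",
        "Dissection hemostasis",
    ],
    "other": [
        "Suction",
        "Camera handling",
        "Changing instrument",
        "Cleaning",
        "Holding with 4. Arm",
        "Holding with other instruments",
        "External instrument (non-robot)",
        "Catheter placement",
    ],
}


@dataclass
class LabelSchema:
    """Two-level behavior schema: category -> list of subcategory names."""

    categories: dict[str, list[str]]

    def __post_init__(self):
        seen: set[str] = set()
        for cat, subs in self.categories.items():
            for sub in subs:
                if sub in seen:
                    raise ValidationError(
                        f"subcategory {sub!r} appears in more than one category"
                    )
                seen.add(sub)
        self._category_of = {
            sub: cat for cat, subs in self.categories.items() for sub in subs
        }

    @property
    def subcategories(self) -> list[str]:
        return [s for subs in self.categories.values() for s in subs]

    def __contains__(self, behavior: str) -> bool:
        return behavior in self._category_of

    def category_of(self, behavior: str) -> str:
        try:
            return self._category_of[behavior]
        except KeyError:
            raise KeyError(f"behavior {behavior!r} is not in the schema") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(categories={str(k): list(v) for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.categories, fh, sort_keys=False,
                           allow_unicode=True)


def default_schema() -> LabelSchema:
    return LabelSchema({k: list(v) for k, v in DEFAULT_SCHEMA_CATEGORIES.items()})


@dataclass(frozen=True)
class LabelEvent:
    """One state change: a behavior starting or stopping at a time."""

    time_s: float
    behavior: str
    status: str  # "START" | "STOP"

    def __post_init__(self):
        if self.time_s < 0:
            raise ValidationError(f"label time must be >= 0, got {self.time_s}")
        if self.status not in ("START", "STOP"):
            raise ValidationError(
                f"status must be START or STOP, got {self.status!r}"
            )


@dataclass(frozen=True)
class LabelInterval:
    """A paired START/STOP span of one behavior."""

    behavior: str
    start_s: float
    stop_s: float

    def __post_init__(self):
        if self.stop_s <= self.start_s:
            raise ValidationError(
                f"interval for {self.behavior!r} must have stop > start, "
                f"got [{self.start_s}, {self.stop_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class CountTable:
    """Per-subcategory interval counts with per-category roll-ups."""

    schema: LabelSchema
    subcategory_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for sub in self.subcategory_counts:
            if sub not in self.schema:
                raise ValidationError(f"count for unknown subcategory {sub!r}")
        for sub in self.schema.subcategories:
            self.subcategory_counts.setdefault(sub, 0)

    @property
    def category_totals(self) -> dict[str, int]:
        totals = {cat: 0 for cat in self.schema.categories}
        for sub, n in self.subcategory_counts.items():
            totals[self.schema.category_of(sub)] += n
        return totals

    @property
    def total(self) -> int:
        return sum(self.subcategory_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "category": cat,
            "subcategory": sub,
            "count": self.subcategory_counts[sub],
            "category_total": self.category_totals[cat],
        } for cat, subs in self.schema.categories.items() for sub in subs]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "subcategories": dict(self.subcategory_counts),
            "categories": self.category_totals,
            "total": self.total,
        }


# ---------------------------------------------------------------------------
# TSV parsing
# ---------------------------------------------------------------------------

_REQUIRED = ("time", "behavior", "status")


def parse_labels(tsv_path: str | Path, schema: LabelSchema | None = None,
                 enforce_schema: bool = True) -> list[LabelEvent]:
    """Parse a behavioral-observation TSV export into label events.

    Column lookup is case-insensitive and extra columns are ignored; the
    exporters add many. Events are returned sorted by time, ties broken by
    file order. With ``enforce_schema`` every behavior must be a known
    subcategory.
    """
    tsv_path = Path(tsv_path)
    if not tsv_path.exists():
        raise ParseError(f"label file not found: {tsv_path}")
    if schema is None:
        schema = default_schema()
    try:
        df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"could not read TSV {tsv_path}: {exc}") from exc
    colmap = {c.lower().strip(): c for c in df.columns}
    missing = [name for name in _REQUIRED if name not in colmap]
    if missing:
        raise ParseError(
            f"{tsv_path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    events: list[LabelEvent] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        raw_time = row[df.columns.get_loc(colmap["time"])]
        behavior = str(row[df.columns.get_loc(colmap["behavior"])]).strip()
        status = str(row[df.columns.get_loc(colmap["status"])]).strip().upper()
        try:
            time_s = float(raw_time)
        except (TypeError, ValueError):
            raise ParseError(
                f"{tsv_path}: unparseable time {raw_time!r} on line {pos}"
            ) from None
        if enforce_schema and behavior not in schema:
            raise ParseError(
                f"{tsv_path}: unknown behavior {behavior!r} on line {pos} "
                f"(schema has: {schema.subcategories})"
            )
        events.append(LabelEvent(time_s=time_s, behavior=behavior, status=status))
    events.sort(key=lambda e: e.time_s)  # stable: ties keep file order
    return events


def serialize_labels(events: Iterable[LabelEvent], path: str | Path) -> None:
    """Write events back out as a minimal three-column TSV."""
    rows = [{"Time": e.time_s, "Behavior": e.behavior, "Status": e.status}
            for e in events]
    pd.DataFrame(rows, columns=["Time", "Behavior", "Status"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval pairing
# ---------------------------------------------------------------------------

def build_intervals(events: Sequence[LabelEvent],
                    strict: bool = False) -> list[LabelInterval]:
    """Pair START/STOP events into intervals, one stack per behavior.

    A STOP closes the most recent open START of the same behavior (LIFO),
    which lets identical behaviors nest; with ``strict`` a nested START of
    an already-open behavior is rejected. Intervals of different behaviors
    interleave freely.
    """
    stacks: dict[str, list[float]] = {}
    intervals: list[LabelInterval] = []
    for ev in events:
        stack = stacks.setdefault(ev.behavior, [])
        if ev.status == "START":
            if strict and stack:
                raise PairingError(
                    f"behavior {ev.behavior!r} starts at {ev.time_s}s while "
                    "already open (strict mode rejects nesting)"
                )
            stack.append(ev.time_s)
        else:
            if not stack:
                raise PairingError(
                    f"STOP for {ev.behavior!r} at {ev.time_s}s has no open START"
                )
            start = stack.pop()
            intervals.append(LabelInterval(ev.behavior, start, ev.time_s))
    dangling = [b for b, s in stacks.items() if s]
    if dangling:
        raise PairingError(
            f"unclosed START(s) at end of file for behavior(s): {sorted(dangling)}"
        )
    intervals.sort(key=lambda iv: (iv.start_s, iv.stop_s, iv.behavior))
    return intervals


# ---------------------------------------------------------------------------
# clip extraction
# ---------------------------------------------------------------------------

def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "-", text).strip("-").lower()


def extract_clips(video: str | Path, intervals: Sequence[LabelInterval],
                  out_dir: str | Path, fps: float | None = None,
                  video_id: str | None = None) -> list[Path]:
    """Cut one clip per interval out of a video.

    Frame ranges are half-open ``[round(start_s*fps), round(stop_s*fps))``,
    so clip lengths are bit-reproducible. Files are named
    ``<video>_<behavior>_<start>s`` in the output directory.
    """
    from .video_io import read_video, write_video

    video = Path(video)
    frames, file_fps = read_video(video, fps=fps)
    n = frames.shape[0]
    if video_id is None:
        video_id = video.stem
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for iv in intervals:
        f0 = int(round(iv.start_s * file_fps))
        f1 = int(round(iv.stop_s * file_fps))
        if f0 < 0 or f1 > n:
            raise ParameterError(
                f"interval [{iv.start_s}, {iv.stop_s})s of {iv.behavior!r} "
                f"exceeds the video duration ({n / file_fps:.3f} s)"
            )
        path = out_dir / f"{video_id}_{_slug(iv.behavior)}_{iv.start_s:g}s{video.suffix}"
        write_video(path, frames[f0:f1], file_fps)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_label_counts(label_sets: Iterable, schema: LabelSchema | None = None,
                           ) -> CountTable:
    """Count paired intervals per subcategory across one or more label files.

    ``label_sets`` may contain file paths or already-parsed event lists.
    Category totals are the sums of their subcategory counts by
    construction.
    """
    if schema is None:
        schema = default_schema()
    counts: dict[str, int] = {}
    for item in label_sets:
        if isinstance(item, (str, Path)):
            events = parse_labels(item, schema=schema)
        else:
            events = list(item)
        for iv in build_intervals(events):
            if iv.behavior not in schema:
                raise ParseError(f"behavior {iv.behavior!r} is not in the schema")
            counts[iv.behavior] = counts.get(iv.behavior, 0) + 1
    return CountTable(schema=schema, subcategory_counts=counts)
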