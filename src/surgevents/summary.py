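"""Cohort summaries: event totals and per-minute rates by procedure and
experience group.

Sessions are grouped into *novice* (fewer than 100 prior robot-assisted
procedures) and *experienced* surgeons, the customary learning-curve
boundary. Exactly 100 prior cases is assigned to the experienced group.
Event counts are reported as mean and sample standard deviation (n-1
denominator) per (procedure, group) cell; with a single session the SD is
undefined and reported as NA. Because session durations vary widely, each
table is emitted both as raw per-session counts and as per-minute rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .event_detection import EventLog
from .exceptions import ParameterError
from .profiles import EventChannel

__all__ = [
    "SessionMeta",
    "classify_experience",
    "per_minute",
    "group_stats",
    "build_event_table",
    "load_session_meta",
    "format_mmss",
]

#: Prior-case boundary between the novice and experienced groups.
EXPERIENCE_BOUNDARY = 100


def classify_experience(total_prior_cases: int) -> str:
    """'novice' below 100 prior robot-assisted cases, else 'experienced'."""
    if total_prior_cases < 0:
        raise ParameterError(
            f"total_prior_cases must be >= 0, got {total_prior_cases}"
        )
    return "novice" if total_prior_cases < EXPERIENCE_BOUNDARY else "experienced"


@dataclass(frozen=True)
class SessionMeta:
    """Descriptors of one recorded session."""

    video_id: str
    procedure: str
    participant_id: str
    total_prior_cases: int
    duration_s: float

    @property
    def group(self) -> str:
        return classify_experience(self.total_prior_cases)


def per_minute(count: int, duration_s: float) -> float:
    """Event rate per minute: ``count / (duration_s / 60)``."""
    if duration_s <= 0:
        raise ParameterError(f"duration_s must be positive, got {duration_s}")
    if count < 0:
        raise ParameterError(f"count must be >= 0, got {count}")
    return count / (duration_s / 60.0)


def group_stats(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1); SD is NaN for a single value."""
    if len(values) == 0:
        raise ParameterError("group_stats needs at least one value")
    arr = np.asarray(values, dtype=np.float64)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
    return mean, sd


def format_mmss(seconds: float) -> str:
    """Duration as an ``mm.ss`` report string (65 s -> ``'01.05'``)."""
    if seconds < 0:
        raise ParameterError(f"duration must be >= 0, got {seconds}")
    m, s = divmod(int(round(seconds)), 60)
    return f"{m:02d}.{s:02d}"


def load_session_meta(path: str | Path) -> list[SessionMeta]:
    """Session metadata CSV: video_id, procedure, participant_id,
    total_prior_cases, duration_s."""
    df = pd.read_csv(path)
    required = ["video_id", "procedure", "participant_id",
                "total_prior_cases", "duration_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError(f"metadata CSV {path} lacks columns: {missing}")
    return [SessionMeta(
        video_id=str(r.video_id), procedure=str(r.procedure),
        participant_id=str(r.participant_id),
        total_prior_cases=int(r.total_prior_cases),
        duration_s=float(r.duration_s),
    ) for r in df.itertuples(index=False)]


def build_event_table(logs: Iterable[EventLog], meta: Iterable[SessionMeta],
                      rates: bool = False) -> pd.DataFrame:
    """Summary table: one row per (procedure, group), mean (SD) per channel.

    ``rates`` switches the summarized quantity from per-session event counts
    to per-minute rates. Columns are ``<channel>_mean`` / ``<channel>_sd``
    for every channel observed anywhere in the cohort, plus ``n_sessions``,
    ``duration_mean_s`` and ``duration_mean_mmss``. Session order never
    affects the result.
    """
    logs = list(logs)
    meta_by_id = {m.video_id: m for m in meta}
    missing = [log.video_id for log in logs if log.video_id not in meta_by_id]
    if missing:
        raise ParameterError(
            f"no session metadata for video_id(s): {sorted(missing)}"
        )

    channels = sorted({ch.value for log in logs for ch in log.counts})
    rows = []
    for log in logs:
        m = meta_by_id[log.video_id]
        duration = m.duration_s if m.duration_s > 0 else log.duration_s
        row = {
            "procedure": m.procedure,
            "group": m.group,
            "duration_s": duration,
        }
        for ch in channels:
            count = log.count(EventChannel(ch))
            row[ch] = per_minute(count, duration) if rates else count
        rows.append(row)
    if not rows:
        return pd.DataFrame()

    df = pd.DataFrame(rows).sort_values(
        ["procedure", "group"], kind="stable")
    out_rows = []
    for (procedure, group), cell in df.groupby(["procedure", "group"],
                                               sort=True):
        out = {"procedure": procedure, "group": group,
               "n_sessions": len(cell)}
        for ch in channels:
            mean, sd = group_stats(cell[ch].tolist())
            out[f"{ch}_mean"] = mean
            out[f"{ch}_sd"] = sd
        dur_mean, _ = group_stats(cell["duration_s"].tolist())
        out["duration_mean_s"] = dur_mean
        out["duration_mean_mmss"] = format_mmss(dur_mean)
        out_rows.append(out)
    return pd.DataFrame(out_rows).set_index(["procedure", "group"])
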