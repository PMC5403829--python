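"""Cleaning of wearable sleep records into a sleep/wake timeline.

Wrist-worn trackers occasionally fragment a single night into several sleep
events separated by short spurious "awake" gaps (often caused by heart-rate
tracking dropouts).  This module merges such fragments, builds the
alternating wake/sleep timeline consumed by the performance model, scores
wear/sleep/session compliance against ideal use, and flags participants
whose records are too incomplete to model.

Merge rule: adjacent events are combined when the gap between them is under
1.5 h, or under 3 h with heart-rate data present for fewer than 85% of the
gap minutes.  Gap minutes with recorded steps count as minutes awake
(ambulatory movement); all other gap minutes count as minutes asleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "SleepEvent",
    "SleepWakeTimeline",
    "merge_fragmented_events",
    "build_timeline",
    "compliance_report",
    "flag_exclusions",
    "main_sleep_events",
]

MERGE_GAP_H = 1.5
MERGE_GAP_LOW_HR_H = 3.0
HR_COVERAGE_THRESHOLD = 0.85
MAIN_SLEEP_MIN_H = 3.0

#: Off-wrist allowance per day of study (one 1.75 h weekly charge plus
#: 15 min daily for bathing comes to 3.5 h over a 7-day week).
OFF_WRIST_ALLOWANCE_H_PER_DAY = 0.5


@dataclass
class SleepEvent:
    """One tracker-reported sleep interval with its minute composition."""

    start: pd.Timestamp
    end: pd.Timestamp
    minutes_asleep: int
    minutes_restless: int = 0
    minutes_awake: int = 0

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.end <= self.start:
            raise InputError("sleep event end must follow its start")

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class SleepWakeTimeline:
    """Contiguous alternating wake/sleep intervals in hours since origin.

    ``origin`` is the first midnight at or before the earliest record so
    fractional hours stay interpretable as clock time.
    """

    origin: pd.Timestamp
    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def arrays(self):
        starts = np.array([s for _, s, _ in self.intervals])
        ends = np.array([e for _, _, e in self.intervals])
        states = [st for st, _, _ in self.intervals]
        wake_anchor = np.empty(len(states))
        last_wake = starts[0] if len(states) else 0.0
        for i, st in enumerate(states):
            if st == "wake":
                last_wake = starts[i]
            wake_anchor[i] = last_wake
        return starts, ends, states, wake_anchor

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0][1], self.intervals[-1][2]

    def state_at(self, t: float) -> str:
        starts = np.array([s for _, s, _ in self.intervals])
        i = int(np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1))
        return self.intervals[i][0]

    def t_w(self, t: float) -> float:
        """Start of the wake interval containing or most recently preceding ``t``."""
        starts, _, _, wake_anchor = self.arrays()
        i = int(np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1))
        return float(wake_anchor[i])

    def hours(self, when) -> np.ndarray:
        """Convert timestamps to fractional hours since the origin."""
        idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(when, dtype="datetime64[ns]")))
        return (idx - self.origin).total_seconds() / 3600.0


def _minute_frame(minutes: pd.DataFrame) -> pd.DataFrame:
    df = minutes.copy()
    if "timestamp" in df.columns:
        df = df.set_index(pd.DatetimeIndex(pd.to_datetime(df["timestamp"])))
    else:
        df.index = pd.DatetimeIndex(pd.to_datetime(df.index))
    return df


def _check_sorted(events: Sequence[SleepEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.start < a.start:
            raise InputError("sleep events must be sorted by start time")
        if b.start < a.end:
            raise InputError("sleep events must not overlap")


def merge_fragmented_events(
    events: Sequence[SleepEvent],
    minutes: pd.DataFrame,
    gap_h: float = MERGE_GAP_H,
    gap_low_hr_h: float = MERGE_GAP_LOW_HR_H,
    hr_coverage: float = HR_COVERAGE_THRESHOLD,
) -> list[SleepEvent]:
    """Merge fragmented sleep events, left to right with cascading.

    Adjacent events merge when the intervening gap is under ``gap_h`` hours,
    or under ``gap_low_hr_h`` hours with heart rate present in fewer than
    ``hr_coverage`` of the gap minutes.  Gap minutes with steps become
    minutes awake; the rest become minutes asleep, so minute bookkeeping is
    conserved.  A merged event is re-examined against the next event, which
    makes the operation idempotent.
    """
    events = [replace(e) for e in events]
    _check_sorted(events)
    if not events:
        return []
    df = _minute_frame(minutes)
    hr = df["hr_bpm"] if "hr_bpm" in df.columns else pd.Series(dtype=float)
    steps = df["steps"] if "steps" in df.columns else pd.Series(dtype=float)

    out: list[SleepEvent] = [events[0]]
    for nxt in events[1:]:
        cur = out[-1]
        gap = (nxt.start - cur.end).total_seconds() / 3600.0
        gap_idx = df.index[(df.index >= cur.end) & (df.index < nxt.start)]
        do_merge = False
        if gap < gap_h:
            do_merge = True
        elif gap < gap_low_hr_h:
            cov = float(hr.loc[gap_idx].notna().mean()) if len(gap_idx) else 1.0
            do_merge = cov < hr_coverage
        if do_merge:
            n_gap = len(gap_idx)
            n_steps = int((steps.loc[gap_idx].fillna(0) > 0).sum()) if n_gap else 0
            out[-1] = SleepEvent(
                start=cur.start,
                end=nxt.end,
                minutes_asleep=cur.minutes_asleep + nxt.minutes_asleep + (n_gap - n_steps),
                minutes_restless=cur.minutes_restless + nxt.minutes_restless,
                minutes_awake=cur.minutes_awake + nxt.minutes_awake + n_steps,
            )
        else:
            out.append(nxt)
    return out


def main_sleep_events(events: Iterable[SleepEvent], min_h: float = MAIN_SLEEP_MIN_H) -> list[SleepEvent]:
    """Cleaned events long enough to count as a night's main sleep."""
    return [e for e in events if e.duration_h >= min_h]


def build_timeline(events: Sequence[SleepEvent], span: tuple) -> SleepWakeTimeline:
    """Fill a study span with alternating wake/sleep intervals.

    Wake intervals fill all time outside the (cleaned) sleep events; first
    and last intervals may be partial.  Restless minutes remain part of the
    sleep interval: the model's wake/sleep branches operate at interval
    granularity.
    """
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if end <= start:
        raise InputError("span end must follow span start")
    events = sorted(events, key=lambda e: e.start)
    _check_sorted(events)
    for e in events:
        if e.start < start or e.end > end:
            raise InputError("cleaned events must lie within the span")
    origin = start.normalize()
    tl = SleepWakeTimeline(origin=origin)

    def h(ts):
        return (pd.Timestamp(ts) - origin).total_seconds() / 3600.0

    cursor = start
    for e in events:
        if e.start > cursor:
            tl.intervals.append(("wake", h(cursor), h(e.start)))
        tl.intervals.append(("sleep", h(e.start), h(e.end)))
        cursor = e.end
    if cursor < end or not tl.intervals:
        tl.intervals.append(("wake", h(cursor), h(end)))
    return tl


def compliance_report(
    minutes: pd.DataFrame,
    events: Sequence[SleepEvent],
    sessions: pd.DataFrame | None,
    span: tuple,
    n_days: int | None = None,
    sessions_per_day: int = 3,
    questions_per_assessment: int = 20,
    pvt_minutes: float = 5.0,
) -> dict:
    """Wear, sleep-night and session compliance as percentages of ideal.

    Ideal wear allows 0.5 h/day off wrist (a 1.75 h weekly charge plus 15 min
    daily bathing = 3.5 h over a week); wear% is capped at 100.  A complete
    session has ``questions_per_assessment`` questions of each non-PVT
    assessment and at least ``pvt_minutes`` of PVT.
    """
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    span_h = (end - start).total_seconds() / 3600.0
    if span_h <= 0:
        raise InputError("span must have positive length")
    span_days = span_h / 24.0
    if n_days is None:
        n_days = int(round(span_days))

    df = _minute_frame(minutes)
    df = df[(df.index >= start) & (df.index < end)]
    worn_min = float(df["hr_bpm"].notna().sum()) if "hr_bpm" in df.columns else 0.0
    allowance_min = OFF_WRIST_ALLOWANCE_H_PER_DAY * span_days * 60.0
    denom = span_h * 60.0 - allowance_min
    wear_pct = min(100.0, 100.0 * worn_min / denom) if denom > 0 else float("nan")

    nights = len(main_sleep_events(events))
    nights_pct = 100.0 * nights / n_days if n_days else float("nan")

    complete = 0
    total_expected = sessions_per_day * n_days
    if sessions is not None and len(sessions):
        s = sessions.copy()
        s["stimulus_time"] = pd.to_datetime(s["stimulus_time"])
        for _, grp in s.groupby("session_id"):
            ok = True
            for assess in ("logical_reasoning", "math_processing", "one_back"):
                if (grp["assessment"] == assess).sum() < questions_per_assessment:
                    ok = False
            pvt = grp[grp["assessment"] == "pvt"]
            if len(pvt) < 2:
                ok = False
            else:
                dur = (pvt["stimulus_time"].max() - pvt["stimulus_time"].min()).total_seconds() / 60.0
                if dur < pvt_minutes - 1e-9:
                    ok = False
            complete += int(ok)
    sessions_pct = 100.0 * complete / total_expected if total_expected else float("nan")
    return {
        "wear_pct": wear_pct,
        "nights_pct": nights_pct,
        "sessions_pct": sessions_pct,
        "n_main_sleep_events": nights,
        "n_complete_sessions": complete,
    }


def flag_exclusions(
    minutes: pd.DataFrame,
    events: Sequence[SleepEvent],
    span: tuple,
    no_sleep_days: int = 3,
    hr_floor: float = 0.5,
) -> list[str]:
    """Exclusion flags for a participant's cleaned records.

    ``NO_DATA``: no wearable records at all.  ``NO_SLEEP_RECORDS``: heart
    rate present (device worn) but a stretch of ``no_sleep_days`` or more
    consecutive days without any sleep event.  ``INTERMITTENT_HR``:
    heart-rate coverage below ``hr_floor``.
    """
    flags: list[str] = []
    df = _minute_frame(minutes) if minutes is not None and len(minutes) else None
    if (df is None or not len(df)) and not events:
        return ["NO_DATA"]
    coverage = float(df["hr_bpm"].notna().mean()) if df is not None and len(df) else 0.0
    if coverage < hr_floor:
        flags.append("INTERMITTENT_HR")

    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if coverage >= hr_floor:
        # longest run of whole days with no sleep event overlapping them
        day_starts = pd.date_range(start.normalize(), end, freq="D")
        run = best = 0
        for d in day_starts[:-1] if len(day_starts) > 1 else day_starts:
            d_end = d + pd.Timedelta(days=1)
            has_sleep = any(e.start < d_end and e.end > d for e in events)
            run = 0 if has_sleep else run + 1
            best = max(best, run)
        if best >= no_sleep_days:
            flags.append("NO_SLEEP_RECORDS")
    return flags
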