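"""Synthetic study cohort generator.

Emulates a one-week wearable + mobile-cognition study: minute-level heart
rate and step records, tracker sleep events (with occasional spurious
fragmentation), and per-question cognitive-session logs for a cohort whose
ground-truth mental acuity follows the modified unified model of
performance.  Every downstream stage of the pipeline (cleaning, feature
extraction, scoring, model fitting) is therefore testable without any real
data, and the true parameters are known.

Design: each session's target score is split across the metric's terms
(logical-reasoning percent correct, PVT SD in CRT, 1-Back SD in CRT) in
equal shares subject to per-term feasibility, and the response log is
constructed so the extracted features hit those targets exactly — correct
counts are exact, and response-time samples are drawn as a symmetric
two-point pattern affinely standardized to the target mean/SD.  With zero
noise, no training effect and no frame quantization, the simulate -> extract
-> score loop is therefore a fixed point of the metric (up to percent
granularity), which is the generator's main correctness oracle.  The price
is that individual response-time marginals are bimodal rather than
lognormal; see the methods note.

Realism knobs: per-device response-time frame quantization and latency
offset, per-minute heart-rate dropout, off-wrist blocks (charging and
bathing), early-session training-effect decay per assessment, sleep-event
fragmentation, and additive Gaussian session noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ump as ump_mod
from .actigraphy import SleepEvent, build_timeline
from .errors import ConfigurationError, InputError

__all__ = [
    "DeviceModel",
    "CohortSpec",
    "TrueParticipant",
    "ParticipantData",
    "CohortData",
    "quantize_rt",
    "generate_sleep_schedule",
    "generate_minute_series",
    "simulate_session_responses",
    "simulate_session",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_PARAM_RANGES",
]

ASSESSMENTS = ("pvt", "logical_reasoning", "math_processing", "one_back")

#: Ground-truth parameter ranges for participant draws.  alpha is negative so
#: that acuity is highest shortly after waking (low sleep pressure) and the
#: circadian period sits near 24 h.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "v": (60.0, 80.0),
    "beta": (6.0, 14.0),
    "tau": (23.7, 24.3),
    "phi": (0.0, 24.0),
    "alpha": (-1.4, -0.6),
    "S0_init": (0.0, 8.0),
    "U": (6.0, 14.0),
    "L0_init": (2.0, 10.0),
}

DEFAULT_HALF_LIVES = {
    "one_back": 0.67,
    "logical_reasoning": 1.5,
    "math_processing": 2.6,
}


@dataclass
class DeviceModel:
    """A phone model with its reporting latency and display refresh rate."""

    name: str
    proportion: float
    latency_offset_ms: float = 0.0
    refresh_hz: float | None = 60.0


def _default_devices() -> tuple[DeviceModel, ...]:
    return (
        DeviceModel("iphone6p", 0.3, 0.0, 60.0),
        DeviceModel("iphone5s", 0.2, 5.0, 60.0),
        DeviceModel("sgs5", 0.3, 25.0, 60.0),
        DeviceModel("motox", 0.2, 15.0, 60.0),
    )


@dataclass
class CohortSpec:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the emulated study: 24 usable participants over 7 days,
    three sessions daily in morning/afternoon/evening windows, nightly sleep
    of 7.3 +/- 0.64 h, and 5 acuity points of session noise.
    """

    n_participants: int = 24
    n_days: int = 7
    sessions_per_day: int = 3
    session_windows: tuple = ((9.0, 12.0), (13.0, 17.0), (17.0, 21.0))
    sleep_duration_mean: float = 7.3
    sleep_duration_sd: float = 0.64
    bedtime_mean: float = 23.5
    bedtime_sd: float = 0.5
    param_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_RANGES))
    noise_sd: float = 5.0
    device_mix: tuple = field(default_factory=_default_devices)
    hr_dropout_rate: float = 0.005
    fragmentation_rate: float = 0.15
    compliance_miss_prob: float = 0.0
    training_amplitude: float = 0.2
    questions_per_assessment: int = 20
    question_timeout_ms: float = 10_000.0
    pvt_minutes: float = 5.0
    pvt_misfire_rate: float = 0.01
    off_wrist: tuple | None = None  # ((day, start_hour, duration_h), ...)
    start_date: str = "2017-01-02"
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.sessions_per_day != len(self.session_windows):
            raise ConfigurationError("sessions_per_day must match session_windows")
        for sd_field in ("sleep_duration_sd", "bedtime_sd", "noise_sd"):
            if getattr(self, sd_field) < 0:
                raise ConfigurationError(f"{sd_field} must be >= 0")
        prev_end = -math.inf
        for w0, w1 in self.session_windows:
            if w1 <= w0 or w0 < prev_end:
                raise ConfigurationError("session_windows must be ordered and non-overlapping")
            prev_end = w1
        total = sum(d.proportion for d in self.device_mix)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("device_mix proportions must sum to 1")
        for rate_field in ("hr_dropout_rate", "fragmentation_rate",
                           "compliance_miss_prob", "pvt_misfire_rate"):
            r = getattr(self, rate_field)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{rate_field} must be in [0, 1]")

    @property
    def origin(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date)

    def default_off_wrist(self) -> tuple:
        """One 1.75 h midweek charge plus a 15-min bathing block each day."""
        blocks = [(min(3, self.n_days - 1), 11.0, 1.75)]
        blocks += [(d, 7.75, 0.25) for d in range(self.n_days)]
        return tuple(blocks)


@dataclass
class TrueParticipant:
    """Ground truth for one synthetic participant."""

    participant_id: str
    ump: ump_mod.UMPParams
    device: DeviceModel
    training_half_lives: dict = field(default_factory=lambda: dict(DEFAULT_HALF_LIVES))
    compliance_miss_prob: float = 0.0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.training_half_lives.values()):
            raise ConfigurationError("training half-lives must be positive")
        if not 0.0 <= self.compliance_miss_prob <= 1.0:
            raise ConfigurationError("compliance_miss_prob must be in [0, 1]")


@dataclass
class ParticipantData:
    truth: TrueParticipant
    sleep_events: list  # tracker view (possibly fragmented)
    minutes: pd.DataFrame
    sessions: pd.DataFrame
    truth_sessions: pd.DataFrame  # session_id, session_index, time_h, score_true
    timeline_true: object
    span: tuple


@dataclass
class CohortData:
    spec: CohortSpec
    participants: dict  # pid -> ParticipantData


# ---------------------------------------------------------------------------
# Response-time quantization


def quantize_rt(rt: float, refresh_hz: float, offset: float = 0.0) -> float:
    """Quantize an RT up to the next display frame boundary.

    Returns ``offset + n * (1000 / refresh_hz)`` for the smallest integer
    ``n >= 0`` such that the quantized value is at least ``rt``.
    """
    if rt < 0:
        raise InputError("rt must be non-negative")
    if refresh_hz <= 0:
        raise InputError("refresh_hz must be positive")
    period = 1000.0 / refresh_hz
    n = max(0, math.ceil((rt - offset) / period - 1e-9))
    return offset + n * period


# ---------------------------------------------------------------------------
# Share allocation (inverse of the mental-acuity metric)

_W = 100.0 / 3.0
_PVT_TWO_LAMBDA = 200.0
_OB_TWO_LAMBDA = 600.0
_PVT_SD_MAX = 580.0   # keeps every generated PVT RT below the 1,250 ms cutoff
_OB_SD_MAX = 4600.0   # keeps every generated 1-Back RT below the 10 s timeout
_SD_MIN = 30.0

_T_MIN_PVT = _W * _PVT_TWO_LAMBDA / _PVT_SD_MAX
_T_MIN_OB = _W * _OB_TWO_LAMBDA / _OB_SD_MAX


def _allocate_terms(ma: float) -> dict[str, float | None]:
    """Split a target score across the three metric terms.

    Equal shares where feasible; the PVT spread term cannot fall below the
    value reachable with CRT SDs bounded by the distracted-answer cutoff, so
    low scores floor it there and push the remainder onto the other terms.
    Very low scores drop assessments entirely (no responses -> 0 share).
    """
    if ma <= 1e-9:
        return {"lr": None, "pvt": None, "ob": None}
    t_pvt = max(ma / 3.0, _T_MIN_PVT)
    t_ob = max((ma - t_pvt) / 2.0, _T_MIN_OB)
    t_lr = ma - t_pvt - t_ob
    if t_lr >= 0.0:
        if t_lr > _W:  # percent correct saturates at 100
            excess = t_lr - _W
            t_lr = _W
            t_pvt += excess / 2.0
            t_ob += excess / 2.0
        return {"lr": t_lr, "pvt": t_pvt, "ob": t_ob}
    t_ob = max(ma / 2.0, _T_MIN_OB)
    t_lr = ma - t_ob
    if t_lr >= 0.0:
        return {"lr": min(t_lr, _W), "pvt": None, "ob": t_ob}
    return {"lr": min(ma, _W), "pvt": None, "ob": None}


def _standardized_two_point(n: int, mean: float, sd: float, rng) -> np.ndarray:
    """n values with exact sample mean/SD, bounded within ~[mean-sd, mean+sd]."""
    base = np.empty(n)
    base[0::2] = 1.0
    base[1::2] = -1.0
    if n % 2 == 1:
        base[-1] = 0.0
    rng.shuffle(base)
    z = (base - base.mean()) / np.std(base, ddof=1)
    return mean + sd * z


def _training_decay(tp: TrueParticipant, assessment: str, session_index: int, amplitude: float) -> float:
    h = tp.training_half_lives.get(assessment)
    if h is None or amplitude == 0.0:
        return 0.0
    return amplitude * 2.0 ** (-session_index / h)


def simulate_session_responses(
    ma_true: float,
    assessment: str,
    session_index: int,
    tp: TrueParticipant,
    rng,
    spec: CohortSpec | None = None,
    session_start: pd.Timestamp | None = None,
    session_id: str = "s0",
) -> list[dict]:
    """Per-question response rows for one assessment of one session.

    The rows are constructed so that the extracted features reproduce the
    share of ``ma_true`` assigned to this assessment's metric term (plus a
    training-effect distortion in early sessions), then passed through the
    device's frame quantization.  ``ma_true <= 0`` yields a timeout-only
    block (the scale's floor: no responses).
    """
    spec = spec or CohortSpec()
    if session_start is None:
        session_start = spec.origin
    if assessment not in ASSESSMENTS:
        raise InputError(f"unknown assessment {assessment!r}")
    alloc = _allocate_terms(ma_true)
    decay = _training_decay(tp, assessment, session_index, spec.training_amplitude)
    dev = tp.device

    def q(rt: float) -> float:
        if dev.refresh_hz:
            return quantize_rt(rt, dev.refresh_hz, dev.latency_offset_ms)
        return rt

    rows: list[dict] = []

    def add(offset_s: float, rt_ms, correct, misfire=0):
        rows.append({
            "session_id": session_id,
            "assessment": assessment,
            "device": dev.name,
            "stimulus_time": session_start + pd.Timedelta(seconds=offset_s),
            "rt_ms": rt_ms,
            "correct": correct,
            "misfire": misfire,
        })

    if assessment == "pvt":
        # stimuli at 2-12 s random intervals until 5 minutes are spanned
        offs = [float(rng.uniform(2.0, 12.0))]
        while offs[-1] - offs[0] < spec.pvt_minutes * 60.0:
            offs.append(offs[-1] + float(rng.uniform(2.0, 12.0)))
        n = len(offs)
        share = alloc["pvt"]
        if share is None:
            for o in offs:
                add(o, np.nan, 0)
            return rows
        sd = min(max(_W * _PVT_TWO_LAMBDA / share, _SD_MIN), _PVT_SD_MAX)
        misfires = rng.random(n) < spec.pvt_misfire_rate
        if n - misfires.sum() < 8:  # keep enough responses for stable statistics
            misfires[:] = False
        n_resp = int(n - misfires.sum())
        mean = max(320.0, sd + 20.0)
        rts = _standardized_two_point(n_resp, mean, sd, rng)
        j = 0
        for i, o in enumerate(offs):
            if misfires[i]:
                add(o, np.nan, 0, misfire=1)
            else:
                add(o, q(float(rts[j])), 1)
                j += 1
        return rows

    n = spec.questions_per_assessment
    pace = 4.5 if assessment != "pvt" else 7.0
    offs = np.arange(n) * pace + 330.0  # non-PVT blocks follow the 5-min PVT

    if assessment == "logical_reasoning":
        share = alloc["lr"]
        if share is None:
            for o in offs:
                add(float(o), np.nan, 0)
            return rows
        pct = np.clip(share / _W * 100.0 * (1.0 - decay), 0.0, 100.0)
        n_correct = int(round(pct / 100.0 * n))
        rt_scale = 1.0 + decay
        rts = rng.lognormal(math.log(2200.0 * rt_scale), 0.35, size=n)
        rts = np.clip(rts, 300.0, spec.question_timeout_ms * 0.9)
        correct_mask = np.zeros(n, dtype=bool)
        correct_mask[rng.permutation(n)[:n_correct]] = True
        for i, o in enumerate(offs):
            add(float(o), q(float(rts[i])), int(correct_mask[i]))
        return rows

    if assessment == "one_back":
        share = alloc["ob"]
        if share is None:
            for o in offs:
                add(float(o), np.nan, 0)
            return rows
        sd = min(max(_W * _OB_TWO_LAMBDA / share * (1.0 + decay), _SD_MIN), _OB_SD_MAX)
        g0 = np.clip(ma_true / 100.0, 0.0, 1.0)
        n_correct = int(np.clip(round(g0 * n), 2, n))
        mean = max(600.0, sd + 50.0)
        crt = _standardized_two_point(n_correct, mean, sd, rng)
        wrong_rts = np.clip(
            rng.lognormal(math.log(1200.0 * (1.0 + decay)), 0.4, size=n - n_correct),
            200.0, spec.question_timeout_ms * 0.9,
        )
        correct_mask = np.zeros(n, dtype=bool)
        correct_mask[rng.permutation(n)[:n_correct]] = True
        jc = jw = 0
        for i, o in enumerate(offs):
            if correct_mask[i]:
                add(float(o), q(float(crt[jc])), 1)
                jc += 1
            else:
                add(float(o), q(float(wrong_rts[jw])), 0)
                jw += 1
        return rows

    # math_processing: realistic but outside the metric
    g0 = np.clip(ma_true / 100.0, 0.0, 1.0)
    if ma_true <= 1e-9:
        for o in offs:
            add(float(o), np.nan, 0)
        return rows
    pct = np.clip(100.0 * g0 * (1.0 - decay), 0.0, 100.0)
    n_correct = int(round(pct / 100.0 * n))
    rts = np.clip(
        rng.lognormal(math.log(1800.0 * (1.0 + decay)), 0.4, size=n),
        300.0, spec.question_timeout_ms * 0.9,
    )
    correct_mask = np.zeros(n, dtype=bool)
    correct_mask[rng.permutation(n)[:n_correct]] = True
    for i, o in enumerate(offs):
        add(float(o), q(float(rts[i])), int(correct_mask[i]))
    return rows


def simulate_session(
    ma_true: float,
    session_index: int,
    tp: TrueParticipant,
    rng,
    spec: CohortSpec | None = None,
    session_start: pd.Timestamp | None = None,
    session_id: str = "s0",
) -> pd.DataFrame:
    """All four assessments of one session, as a response DataFrame."""
    rows: list[dict] = []
    for assessment in ASSESSMENTS:
        rows.extend(
            simulate_session_responses(
                ma_true, assessment, session_index, tp, rng,
                spec=spec, session_start=session_start, session_id=session_id,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sleep and wearable records


def _draw_nights(spec: CohortSpec, rng) -> list[tuple[float, float]]:
    """(start_h, end_h) of each night's true sleep, hours since origin."""
    nights = []
    prev_end = -math.inf
    for d in range(spec.n_days):
        bed = d * 24.0 + float(rng.normal(spec.bedtime_mean, spec.bedtime_sd))
        dur = float(np.clip(rng.normal(spec.sleep_duration_mean, spec.sleep_duration_sd), 2.0, 12.0))
        bed = max(bed, prev_end + 0.5)
        nights.append((bed, bed + dur))
        prev_end = bed + dur
    return nights


def _night_event(spec: CohortSpec, start_h: float, end_h: float, rng) -> SleepEvent:
    dur_min = int(round((end_h - start_h) * 60.0))
    restless = int(rng.integers(3, 15))
    return SleepEvent(
        start=spec.origin + pd.Timedelta(hours=start_h),
        end=spec.origin + pd.Timedelta(hours=end_h),
        minutes_asleep=dur_min - restless,
        minutes_restless=restless,
        minutes_awake=0,
    )


def _fragment(spec: CohortSpec, nights, rng):
    """Tracker view of the nights: some split into two events by a short gap."""
    events: list[SleepEvent] = []
    gaps: list[tuple[float, float]] = []
    for start_h, end_h in nights:
        dur = end_h - start_h
        if rng.random() < spec.fragmentation_rate and dur > 2.0:
            gap = float(rng.uniform(0.1, 1.4))
            cut = float(rng.uniform(0.5, dur - gap - 0.5))
            events.append(_night_event(spec, start_h, start_h + cut, rng))
            events.append(_night_event(spec, start_h + cut + gap, end_h, rng))
            gaps.append((start_h + cut, start_h + cut + gap))
        else:
            events.append(_night_event(spec, start_h, end_h, rng))
    return events, gaps


def generate_sleep_schedule(tp: TrueParticipant, spec: CohortSpec, rng) -> list[SleepEvent]:
    """Tracker sleep events for one participant (one main event per night,
    occasionally fragmented into two sub-events separated by a gap < 1.5 h)."""
    spec.validate()
    nights = _draw_nights(spec, rng)
    events, _ = _fragment(spec, nights, rng)
    return events


def generate_minute_series(
    events,
    spec: CohortSpec,
    rng,
    span: tuple | None = None,
    quiet_spans=None,
    off_wrist=None,
) -> pd.DataFrame:
    """Minute-grid heart rate and steps over the study span.

    Heart rate is present except at dropout minutes and off-wrist blocks;
    steps are zero during sleep and sporadic during wake.  ``quiet_spans``
    (hours since origin) mark fragmentation gaps where the participant was
    actually asleep, so steps there are rare.
    """
    origin = spec.origin
    if span is None:
        end_h = max(
            [spec.n_days * 24.0]
            + [(pd.Timestamp(e.end) - origin).total_seconds() / 3600.0 for e in events]
        )
        span = (origin, origin + pd.Timedelta(hours=math.ceil(end_h)))
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    for e in events:
        if e.start < start or e.end > end:
            raise InputError("sleep events must lie within the study span")
    idx = pd.date_range(start, end, freq="min", inclusive="left")
    n = len(idx)
    hours = (idx - origin).total_seconds().to_numpy() / 3600.0

    asleep = np.zeros(n, dtype=bool)
    for e in events:
        asleep |= (idx >= e.start) & (idx < e.end)
    quiet = np.zeros(n, dtype=bool)
    for a, b in quiet_spans or []:
        quiet |= (hours >= a) & (hours < b)

    hr = np.where(asleep, 55.0, 72.0) + rng.normal(0.0, 3.0, size=n)
    dropout = rng.random(n) < spec.hr_dropout_rate
    hr[dropout] = np.nan

    off = np.zeros(n, dtype=bool)
    blocks = spec.default_off_wrist() if off_wrist is None and spec.off_wrist is None else (
        off_wrist if off_wrist is not None else spec.off_wrist
    )
    for day, start_hour, dur_h in blocks or []:
        a = day * 24.0 + start_hour
        off |= (hours >= a) & (hours < a + dur_h)
    hr[off] = np.nan

    wake_active = (~asleep) & (~quiet) & (~off)
    stepping = wake_active & (rng.random(n) < 0.5)
    stepping |= quiet & (rng.random(n) < 0.05)
    steps = np.where(stepping, rng.poisson(14.0, size=n), 0)
    steps[asleep] = 0

    return pd.DataFrame({"timestamp": idx, "hr_bpm": np.round(hr, 1), "steps": steps})


# ---------------------------------------------------------------------------
# Whole-cohort generation


def _draw_participant(i: int, spec: CohortSpec, rng) -> TrueParticipant:
    ranges = spec.param_ranges
    kw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
    dev_idx = int(rng.choice(len(spec.device_mix), p=[d.proportion for d in spec.device_mix]))
    return TrueParticipant(
        participant_id=f"A{i + 1:02d}",
        ump=ump_mod.UMPParams(**kw),
        device=spec.device_mix[dev_idx],
        compliance_miss_prob=spec.compliance_miss_prob,
    )


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate wearable records, session logs and ground truth for a cohort.

    Deterministic given ``spec.seed``; per-participant RNG substreams are
    derived from the seed so any single participant regenerates identically.
    """
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_participants)
    participants: dict[str, ParticipantData] = {}
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        tp = _draw_participant(i, spec, rng)
        pid = tp.participant_id

        nights = _draw_nights(spec, rng)
        events, gaps = _fragment(spec, nights, rng)
        end_h = math.ceil(max(spec.n_days * 24.0, max(e for _, e in nights) + 1.0))
        span = (spec.origin, spec.origin + pd.Timedelta(hours=end_h))
        minutes = generate_minute_series(events, spec, rng, span=span, quiet_spans=gaps)

        truth_events = [_night_event(spec, a, b, rng) for a, b in nights]
        timeline = build_timeline(truth_events, span)

        times = []
        for d in range(spec.n_days):
            for w0, w1 in spec.session_windows:
                if rng.random() < tp.compliance_miss_prob:
                    continue
                times.append(d * 24.0 + float(rng.uniform(w0, w1)))
        times.sort()
        scores_true = ump_mod.predict(tp.ump, timeline, times) if times else np.array([])

        frames = []
        truth_rows = []
        for s_idx, (t, sc) in enumerate(zip(times, scores_true)):
            sid = f"{pid}-s{s_idx:02d}"
            ma_obs = float(sc + rng.normal(0.0, spec.noise_sd))
            start_ts = spec.origin + pd.Timedelta(hours=t)
            frames.append(
                simulate_session(ma_obs, s_idx, tp, rng, spec=spec,
                                 session_start=start_ts, session_id=sid)
            )
            truth_rows.append({
                "session_id": sid, "session_index": s_idx,
                "time_h": t, "score_true": float(sc), "score_observed": ma_obs,
            })
        sessions = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["session_id", "assessment", "device", "stimulus_time",
                     "rt_ms", "correct", "misfire"]
        )
        participants[pid] = ParticipantData(
            truth=tp,
            sleep_events=events,
            minutes=minutes,
            sessions=sessions,
            truth_sessions=pd.DataFrame(truth_rows),
            timeline_true=timeline,
            span=span,
        )
    return CohortData(spec=spec, participants=participants)


def write_cohort(data: CohortData, outdir) -> None:
    """Write per-participant CSVs and the ground-truth bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": data.spec.seed, "participants": {}}
    for pid, pdata in data.participants.items():
        pdata.minutes.to_csv(outdir / f"minutes_{pid}.csv", index=False)
        pd.DataFrame(
            [{
                "start": e.start.isoformat(), "end": e.end.isoformat(),
                "minutes_asleep": e.minutes_asleep,
                "minutes_restless": e.minutes_restless,
                "minutes_awake": e.minutes_awake,
            } for e in pdata.sleep_events]
        ).to_csv(outdir / f"sleep_{pid}.csv", index=False)
        s = pdata.sessions.copy()
        s["stimulus_time"] = pd.to_datetime(s["stimulus_time"]).map(
            lambda t: t.isoformat()
        )
        s.to_csv(outdir / f"sessions_{pid}.csv", index=False)
        truth["participants"][pid] = {
            "ump": pdata.truth.ump.to_dict(),
            "device": dataclasses.asdict(pdata.truth.device),
            "training_half_lives": dict(pdata.truth.training_half_lives),
            "sessions": pdata.truth_sessions.to_dict(orient="records"),
            "span": [str(pdata.span[0]), str(pdata.span[1])],
        }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
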