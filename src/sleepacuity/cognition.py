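"""Cognitive-session feature extraction and quality control.

Each mobile assessment session comprises four tasks: a 5-min psychomotor
vigilance test (PVT), logical reasoning, math processing and a 1-Back
working-memory test.  From the per-question response log this module
computes the per-assessment feature battery (response-time statistics,
correctness counts/rates, and the PVT-specific lapse / distracted / misfire
counts), fits the exponential training-effect decay observed over early
sessions, tests for systematic response-time bias between phone models, and
detects frame-clock discretization of reported response times.

PVT conventions: a lapse is a response slower than 500 ms (strictly
greater); a distracted answer is slower than 1,250 ms and excluded from the
RT/CRT statistics (distracted answers still count as lapses, since the
thresholds nest); a misfire is a response before stimulus onset, excluded
from RT statistics; an incorrect PVT "answer" is a timeout or a misfire.
Features are only computed for assessments with more than five answered
questions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InputError, InsufficientDataError

__all__ = [
    "ASSESSMENTS",
    "LAPSE_MS",
    "DISTRACTED_MS",
    "MIN_ANSWERED",
    "AssessmentFeatures",
    "SessionFeatures",
    "extract_features",
    "build_feature_matrix",
    "TrainingEffectModel",
    "fit_training_effect",
    "sessions_to_exclude",
    "device_bias_test",
    "detect_discretization",
]

ASSESSMENTS = ("pvt", "logical_reasoning", "math_processing", "one_back")
LAPSE_MS = 500.0
DISTRACTED_MS = 1250.0
MIN_ANSWERED = 5  # features require strictly more answered questions

_STATS = (
    "rt_mean", "rt_median", "rt_sd",
    "crt_mean", "crt_median", "crt_sd",
    "correct_count", "correct_rate", "correct_pct",
    "incorrect_count", "timeout_count",
)
_PVT_STATS = ("lapse_count", "distracted_count", "misfire_count")


@dataclass
class AssessmentFeatures:
    """Feature values for one assessment within one session."""

    valid: bool
    values: dict[str, float] = field(default_factory=dict)

    def get(self, name: str) -> float:
        return self.values.get(name, float("nan"))


@dataclass
class SessionFeatures:
    """Per-assessment features for one session."""

    session_id: str
    assessments: dict[str, AssessmentFeatures] = field(default_factory=dict)

    def flat(self) -> dict[str, float]:
        """Flatten to ``{"<assessment>.<stat>": value}`` (invalid -> NaN)."""
        out: dict[str, float] = {}
        for assess, feats in self.assessments.items():
            names = _STATS + (_PVT_STATS if assess == "pvt" else ())
            for name in names:
                out[f"{assess}.{name}"] = feats.get(name) if feats.valid else float("nan")
        return out


def _stat_block(rts: np.ndarray, prefix: str) -> dict[str, float]:
    if rts.size == 0:
        return {f"{prefix}_mean": float("nan"), f"{prefix}_median": float("nan"),
                f"{prefix}_sd": float("nan")}
    sd = float(np.std(rts, ddof=1)) if rts.size >= 2 else float("nan")
    return {
        f"{prefix}_mean": float(np.mean(rts)),
        f"{prefix}_median": float(np.median(rts)),
        f"{prefix}_sd": sd,
    }


def extract_features(responses: pd.DataFrame) -> SessionFeatures:
    """Compute the feature battery for one session's response log.

    Expects columns ``session_id, assessment, stimulus_time, rt_ms, correct,
    misfire`` (empty ``rt_ms`` with ``misfire == 0`` marks a timeout).
    RT statistics exclude timeouts; CRT statistics are restricted to correct
    responses; PVT statistics additionally exclude misfires and distracted
    answers.
    """
    ids = responses["session_id"].unique()
    if len(ids) != 1:
        raise InputError("extract_features expects responses from a single session")
    sf = SessionFeatures(session_id=str(ids[0]))
    stim = pd.to_datetime(responses["stimulus_time"])

    for assess in ASSESSMENTS:
        grp = responses[responses["assessment"] == assess]
        if grp.empty:
            continue
        rt = pd.to_numeric(grp["rt_ms"], errors="coerce").to_numpy(dtype=float)
        misfire = grp["misfire"].fillna(0).astype(int).to_numpy() if "misfire" in grp else np.zeros(len(grp), int)
        timeout = np.isnan(rt) & (misfire == 0)
        answered = ~timeout  # misfires count as responses
        n_total = len(grp)
        n_answered = int(answered.sum())
        if n_answered <= MIN_ANSWERED:
            sf.assessments[assess] = AssessmentFeatures(valid=False)
            continue

        values: dict[str, float] = {}
        responded = answered & (misfire == 0)
        if assess == "pvt":
            resp_rt = rt[responded]
            lapse = int((resp_rt > LAPSE_MS).sum())
            distracted = int((resp_rt > DISTRACTED_MS).sum())
            values["lapse_count"] = float(lapse)
            values["distracted_count"] = float(distracted)
            values["misfire_count"] = float(misfire.sum())
            stat_rt = resp_rt[resp_rt <= DISTRACTED_MS]
            correct = responded  # responded in time = correct for PVT
            incorrect = timeout | (misfire == 1)
            crt = stat_rt  # correct responses, minus distracted, for statistics
        else:
            corr = pd.to_numeric(grp["correct"], errors="coerce").fillna(0).astype(int).to_numpy()
            stat_rt = rt[responded]
            correct = responded & (corr == 1)
            incorrect = responded & (corr == 0)
            crt = rt[correct]

        values.update(_stat_block(stat_rt, "rt"))
        values.update(_stat_block(crt, "crt"))
        n_correct = int(correct.sum())
        values["correct_count"] = float(n_correct)
        values["incorrect_count"] = float(incorrect.sum())
        values["timeout_count"] = float(timeout.sum())
        values["correct_pct"] = 100.0 * n_correct / n_total if n_total else float("nan")

        st = pd.to_datetime(grp["stimulus_time"])
        t0 = st.min()
        end_candidates = st + pd.to_timedelta(np.nan_to_num(rt, nan=0.0), unit="ms")
        duration_min = (end_candidates.max() - t0).total_seconds() / 60.0
        values["correct_rate"] = n_correct / duration_min if duration_min > 0 else float("nan")
        sf.assessments[assess] = AssessmentFeatures(valid=True, values=values)
    return sf


def build_feature_matrix(responses: pd.DataFrame, origin) -> pd.DataFrame:
    """Session-by-feature matrix from a participant's full response log.

    Rows are ordered by session time; the index holds fractional hours since
    ``origin`` (session start = first stimulus).  Also carries ``session_id``
    and a 0-based ``session_index`` column.
    """
    origin = pd.Timestamp(origin)
    rows = []
    responses = responses.copy()
    responses["stimulus_time"] = pd.to_datetime(responses["stimulus_time"])
    order = responses.groupby("session_id")["stimulus_time"].min().sort_values()
    for s_idx, (sid, t0) in enumerate(order.items()):
        feats = extract_features(responses[responses["session_id"] == sid])
        row = feats.flat()
        row["session_id"] = sid
        row["session_index"] = s_idx
        row["time_h"] = (t0 - origin).total_seconds() / 3600.0
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("time_h").sort_index()
    return df


# ---------------------------------------------------------------------------
# Training effect


@dataclass
class TrainingEffectFit:
    half_life: float
    amplitude: float
    asymptote: float
    converged: bool
    flagged: bool = False


class TrainingEffectModel(RegressorMixin, BaseEstimator):
    """Exponential training-effect decay ``y(s) = c + a * 2**(-s / h)``.

    Early repeated exposure to an assessment improves (or inflates) a feature
    with half-life ``h`` measured in sessions.  Fitted by bounded least
    squares; a flat series leaves ``h`` unidentifiable and is flagged.
    """

    def __init__(self, max_half_life: float = 100.0):
        self.max_half_life = max_half_life

    def fit(self, X, y):
        s = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if s.size != y.size:
            raise InputError("X and y must align")
        if s.size < 4:
            raise InsufficientDataError("training-effect fit needs at least 4 sessions")
        scale = float(np.std(y))
        if scale < 1e-12 * max(1.0, abs(float(np.mean(y)))) or scale == 0.0:
            self.fit_ = TrainingEffectFit(
                half_life=float("nan"), amplitude=0.0,
                asymptote=float(np.mean(y)), converged=True, flagged=True,
            )
            return self

        def resid(theta):
            c, a, h = theta
            return c + a * np.power(2.0, -s / h) - y

        y0, yend = y[np.argmin(s)], y[np.argmax(s)]
        x0 = np.array([yend, y0 - yend if abs(y0 - yend) > 1e-12 else scale, 1.5])
        lo = [-np.inf, -np.inf, 1e-3]
        hi = [np.inf, np.inf, self.max_half_life]
        x0[2] = min(max(x0[2], lo[2] * 2), hi[2] / 2)
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi))
        c, a, h = sol.x
        flagged = (not sol.success) or abs(a) < 1e-6 * max(scale, 1.0) or h >= self.max_half_life * 0.999
        self.fit_ = TrainingEffectFit(
            half_life=float(h), amplitude=float(a), asymptote=float(c),
            converged=bool(sol.success), flagged=bool(flagged),
        )
        return self

    def predict(self, X):
        s = np.asarray(X, dtype=float).reshape(-1)
        f = self.fit_
        if f.flagged and math.isnan(f.half_life):
            return np.full_like(s, f.asymptote)
        return f.asymptote + f.amplitude * np.power(2.0, -s / f.half_life)


def fit_training_effect(series, session_index=None) -> TrainingEffectFit:
    """Fit ``c + a * 2**(-s/h)`` to per-session feature values.

    ``series`` is ordered by session; ``session_index`` defaults to
    ``0..n-1``.  Returns the fitted half-life (sessions), amplitude and
    asymptote; degenerate series come back flagged.
    """
    y = np.asarray(series, dtype=float)
    s = np.arange(y.size) if session_index is None else np.asarray(session_index, dtype=float)
    return TrainingEffectModel().fit(s, y).fit_


def sessions_to_exclude(half_lives: Sequence[float]) -> int:
    """Smallest whole number of sessions strictly greater than every half-life."""
    hl = [float(h) for h in half_lives]
    if not hl:
        return 0
    if any(h <= 0 for h in hl):
        raise InputError("half-lives must be positive")
    return int(math.floor(max(hl))) + 1


# ---------------------------------------------------------------------------
# Device QC


def device_bias_test(rts_by_device: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal–Wallis omnibus and pairwise tests of RT by phone model."""
    groups = {k: np.asarray(v, dtype=float) for k, v in rts_by_device.items()}
    if len(groups) < 2:
        raise InputError("device bias test needs at least 2 device groups")
    for k, v in groups.items():
        if v.size < 5:
            raise InputError(f"device group {k!r} has fewer than 5 RTs")
    H, p = stats.kruskal(*groups.values())
    pairwise = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        _, pp = stats.kruskal(groups[a], groups[b])
        pairwise[(a, b)] = float(pp)
    return {"H": float(H), "p": float(p), "pairwise": pairwise}


def detect_discretization(
    rts: Sequence[float],
    binwidth: float = 8.33,
    max_lag: int = 50,
    min_autocorr: float = 0.25,
) -> float | None:
    """Estimate the dominant spacing of a response-time histogram.

    Frame-locked reporting on a display refreshing at ``f`` Hz quantizes RTs
    to multiples of ``1000/f`` ms, producing a periodic occupied-bin pattern
    in a fine histogram.  Periodicity is established from the autocorrelation
    of the bin counts (lag >= 2 bins); ``None`` is returned when no period
    stands at least twice above the background autocorrelation (and above
    ``min_autocorr`` absolutely).  Because the frame period need not be an
    integer number of bins, the spacing itself is then refined as the median
    gap between adjacent occupied RT positions, which resolves sub-bin
    periods (e.g. 11.1 ms at 90 Hz under 8.33 ms bins).
    """
    x = np.asarray(rts, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 200:
        raise InsufficientDataError("discretization detection needs at least 200 RTs")
    lo, hi = float(x.min()), float(x.max())
    edges = np.arange(lo, hi + 2 * binwidth, binwidth)
    counts, _ = np.histogram(x, bins=edges)
    c = counts - counts.mean()
    ac = np.correlate(c, c, mode="full")[len(c) - 1:]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    L = min(max_lag, len(ac) - 1)
    if L < 2:
        return None
    lags = np.arange(2, L + 1)
    vals = ac[2:L + 1]
    l_star = int(lags[np.argmax(vals)])
    peak = float(ac[l_star])
    background = float(np.median(np.abs(ac[1:L + 1])))
    if peak < max(2.0 * background, min_autocorr):
        return None
    refined = _occupied_gap_spacing(x, merge_tol=binwidth / 8.0)
    return refined if refined is not None else l_star * binwidth


def _occupied_gap_spacing(x: np.ndarray, merge_tol: float) -> float | None:
    """Median gap between adjacent occupied RT positions (cluster centers)."""
    vals = np.sort(np.unique(np.round(x, 3)))
    centers: list[float] = []
    cluster = [vals[0]]
    for v in vals[1:]:
        if v - cluster[-1] <= merge_tol:
            cluster.append(v)
        else:
            centers.append(float(np.mean(cluster)))
            cluster = [v]
    centers.append(float(np.mean(cluster)))
    if len(centers) < 3:
        return None
    return float(np.median(np.diff(centers)))
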