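"""Modified unified model of performance (UMP).

The model expresses a mental-acuity score as

    MA(t) = v + beta * [0.97 sin(2*pi*(t - t_w + phi) / tau)] + alpha * S(t)

where the circadian oscillation is anchored to the most recent wake-up time
``t_w`` and ``S`` is a homeostatic sleep-pressure state with closed-form
first-order dynamics.  During wake, ``S`` relaxes toward the reservoir
capacity ``U`` with time constant ``tau_w``; during sleep it discharges
toward a slowly moving lower reservoir ``L`` (itself relaxing toward ``-2U``
with time constant ``tau_LA``) with time constant ``tau_s``:

    wake:  S(t0 + d) = S0 e^{-d/tau_w} + U (1 - e^{-d/tau_w})
    sleep: S(t0 + d) = S0 e^{-d/tau_s} - 2U (1 - e^{-d/tau_s})
                       + (L0 + 2U) * tau_LA/(tau_LA - tau_s)
                         * (e^{-d/tau_LA} - e^{-d/tau_s})

and, between one interval onset and the next,

    L0 after a wake period:  U + (L0_prev - U) e^{-d/tau_LA}
    L0 after a sleep period: L0_prev e^{-d/tau_LA} - 2U (1 - e^{-d/tau_LA}).

Because every branch is the exact solution of its ODE, interval chaining is
a semigroup: evaluating through a split point equals direct evaluation.
That property is used as the implementation's correctness oracle.

Time constants default to tau_w = 10 h, tau_s = 2 h, tau_LA = 166 h and the
circadian amplitude to 0.97; the remaining eight parameters
(v, beta, tau, phi, alpha, S0_init, U, L0_init) are free and fitted by
bounded nonlinear least squares with seeded multi-start.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FittingError, InputError

__all__ = [
    "UMPParams",
    "FitResult",
    "circadian",
    "propagate_reservoir",
    "homeostatic",
    "predict",
    "fit",
    "fit_group",
    "fit_quality",
    "cross_validate_group",
    "cross_validate_individual",
    "UnifiedPerformanceModel",
    "DEFAULT_BOUNDS",
]

WAKE = "wake"
SLEEP = "sleep"

#: Order of the free (fitted) parameters.
FREE_PARAMS = ("v", "beta", "tau", "phi", "alpha", "S0_init", "U", "L0_init")

#: Default box bounds for the free parameters.  tau is constrained to a
#: physiological circadian band; phi spans a full period.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "v": (-100.0, 200.0),
    "beta": (-50.0, 50.0),
    "tau": (20.0, 28.0),
    "phi": (0.0, 28.0),
    "alpha": (-20.0, 20.0),
    "S0_init": (-150.0, 150.0),
    "U": (1e-3, 50.0),
    "L0_init": (-150.0, 150.0),
}


@dataclass
class UMPParams:
    """Parameters of the modified unified model of performance.

    ``v`` (vertical shift), ``beta`` (circadian scaling), ``tau`` (circadian
    period, hours), ``phi`` (circadian offset relative to waking, hours),
    ``alpha`` (homeostatic scaling), ``S0_init`` (homeostatic state at the
    timeline start), ``U`` (upper reservoir limit), ``L0_init`` (lower
    reservoir limit at the timeline start).  The time constants and the
    circadian amplitude are fixed by default.
    """

    v: float
    beta: float
    tau: float
    phi: float
    alpha: float
    S0_init: float
    U: float
    L0_init: float
    tau_w: float = 10.0
    tau_s: float = 2.0
    tau_LA: float = 166.0
    circ_amp: float = 0.97

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InputError("tau must be positive")

    def free_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FREE_PARAMS], dtype=float)

    @classmethod
    def from_free_array(cls, x: Sequence[float], **fixed) -> "UMPParams":
        kw = dict(zip(FREE_PARAMS, map(float, x)))
        kw.update(fixed)
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FitResult:
    """Outcome of a least-squares UMP fit."""

    params: UMPParams
    residuals: np.ndarray
    rmse: float
    fit_quality: float
    converged: bool
    n_obs: int
    cost: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "rmse": self.rmse,
            "fit_quality": self.fit_quality,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "cost": self.cost,
        }


def circadian(t, t_w, params: UMPParams):
    """Circadian component ``0.97 sin(2 pi (t - t_w + phi) / tau)``.

    ``tau`` is the period of the oscillation, so it enters as the angular
    frequency ``2 pi / tau``.
    """
    t = np.asarray(t, dtype=float)
    return params.circ_amp * np.sin(
        2.0 * np.pi * (t - np.asarray(t_w, dtype=float) + params.phi) / params.tau
    )


def propagate_reservoir(L0_prev: float, dt: float, prev_state: str, params: UMPParams) -> float:
    """Advance the lower-reservoir limit across one completed interval.

    After a wake period the reservoir relaxes toward ``U``; after a sleep
    period it relaxes toward ``-2U``, both with time constant ``tau_LA``.
    """
    if dt < 0:
        raise InputError("dt must be non-negative")
    e = math.exp(-dt / params.tau_LA)
    if prev_state == WAKE:
        return params.U + (L0_prev - params.U) * e
    if prev_state == SLEEP:
        return L0_prev * e - 2.0 * params.U * (1.0 - e)
    raise InputError(f"unknown interval state {prev_state!r}")


def homeostatic(t, t0: float, state: str, S0: float, L0: float, params: UMPParams):
    """Closed-form homeostatic state at time ``t`` within one interval.

    ``t0`` is the interval onset, ``S0`` the state at onset, ``L0`` the
    lower-reservoir limit at onset (used only during sleep).
    """
    t = np.asarray(t, dtype=float)
    d = t - t0
    if np.any(d < -1e-9):
        raise InputError("query time precedes interval start")
    d = np.maximum(d, 0.0)
    if state == WAKE:
        e = np.exp(-d / params.tau_w)
        return S0 * e + params.U * (1.0 - e)
    if state == SLEEP:
        es = np.exp(-d / params.tau_s)
        ela = np.exp(-d / params.tau_LA)
        k = params.tau_LA / (params.tau_LA - params.tau_s)
        return (
            S0 * es
            - 2.0 * params.U * (1.0 - es)
            + (L0 + 2.0 * params.U) * k * (ela - es)
        )
    raise InputError(f"unknown interval state {state!r}")


def _chain(params: UMPParams, starts, ends, states):
    """Per-interval (S0, L0) obtained by chaining closed forms."""
    n = len(starts)
    S0s = np.empty(n)
    L0s = np.empty(n)
    S0s[0] = params.S0_init
    L0s[0] = params.L0_init
    for i in range(1, n):
        dt = ends[i - 1] - starts[i - 1]
        S0s[i] = float(
            homeostatic(ends[i - 1], starts[i - 1], states[i - 1], S0s[i - 1], L0s[i - 1], params)
        )
        L0s[i] = propagate_reservoir(L0s[i - 1], dt, states[i - 1], params)
    return S0s, L0s


def predict(params: UMPParams, timeline, times) -> np.ndarray:
    """Evaluate the model over a sleep/wake timeline at the given hours.

    The homeostatic state is chained across intervals (the terminal value of
    one interval seeds the next); the circadian term is anchored to the start
    of the current (or most recent) wake interval.  The circadian anchor
    resets at each wake onset, so the full prediction may jump there even
    though the homeostatic term is continuous.
    """
    starts, ends, states, wake_anchor = timeline.arrays()
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size and (times.min() < starts[0] - 1e-6 or times.max() > ends[-1] + 1e-6):
        raise InputError("query time outside timeline span")
    S0s, L0s = _chain(params, starts, ends, states)
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(starts) - 1)
    out = np.empty_like(times)
    sleep_states = np.array([s == SLEEP for s in states])
    for state_is_sleep in (False, True):
        m = sleep_states[idx] == state_is_sleep
        if not m.any():
            continue
        ii = idx[m]
        d = times[m] - starts[ii]
        if state_is_sleep:
            es = np.exp(-d / params.tau_s)
            ela = np.exp(-d / params.tau_LA)
            k = params.tau_LA / (params.tau_LA - params.tau_s)
            out[m] = (
                S0s[ii] * es
                - 2.0 * params.U * (1.0 - es)
                + (L0s[ii] + 2.0 * params.U) * k * (ela - es)
            )
        else:
            e = np.exp(-d / params.tau_w)
            out[m] = S0s[ii] * e + params.U * (1.0 - e)
    circ = circadian(times, wake_anchor[idx], params)
    return params.v + params.beta * circ + params.alpha * out


def fit_quality(observations, predictions) -> float:
    """SD of the observations divided by the RMSE of the predictions.

    The population (divide-by-n) SD is used, so a constant predictor at the
    observation mean scores exactly 1; values above 1 mean the model beats a
    sleep-independent constant.
    """
    obs = np.asarray(observations, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    if obs.shape != pred.shape:
        raise InputError("observations and predictions must have equal length")
    if obs.size < 2:
        raise InputError("need at least 2 observations")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    sd = float(np.std(obs))
    if rmse == 0.0:
        return float("inf")
    return sd / rmse


def _multi_start_points(bounds_lo, bounds_hi, n_starts, rng_seed, y_mean):
    d = len(bounds_lo)
    sampler = qmc.LatinHypercube(d=d, seed=rng_seed)
    unit = sampler.random(n=n_starts)
    pts = bounds_lo + unit * (bounds_hi - bounds_lo)
    i_v = FREE_PARAMS.index("v")
    i_tau = FREE_PARAMS.index("tau")
    pts[:, i_v] = np.clip(y_mean, bounds_lo[i_v] + 1e-9, bounds_hi[i_v] - 1e-9)
    pts[0, i_tau] = np.clip(24.0, bounds_lo[i_tau] + 1e-9, bounds_hi[i_tau] - 1e-9)
    return pts


def _fit_datasets(
    datasets: Sequence[tuple[np.ndarray, np.ndarray, object]],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int | None = 0,
    max_nfev: int | None = None,
    fixed: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit one shared parameter vector to one or more (times, scores, timeline)."""
    fixed = dict(fixed or {})
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b[k][0] for k in FREE_PARAMS])
    hi = np.array([b[k][1] for k in FREE_PARAMS])

    prepared = []
    n_total = 0
    for times, scores, timeline in datasets:
        times = np.asarray(times, dtype=float)
        scores = np.asarray(scores, dtype=float)
        if times.shape != scores.shape:
            raise InputError("times and scores must align")
        prepared.append((times, scores, timeline))
        n_total += times.size
    if n_total < len(FREE_PARAMS):
        raise FittingError(
            f"need at least {len(FREE_PARAMS)} observations, got {n_total}"
        )
    all_scores = np.concatenate([s for _, s, _ in prepared])

    def residuals(x):
        p = UMPParams.from_free_array(x, **fixed)
        res = [predict(p, tl, t) - s for t, s, tl in prepared]
        return np.concatenate(res)

    starts = _multi_start_points(lo, hi, n_starts, seed, float(all_scores.mean()))
    best = None
    any_ok = False
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", max_nfev=max_nfev
            )
        except Exception:
            continue
        any_ok = any_ok or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FittingError("all optimizer starts failed")
    params = UMPParams.from_free_array(best.x, **fixed)
    res = residuals(best.x)
    rmse = float(np.sqrt(np.mean(res**2)))
    fq = float("inf") if rmse == 0 else float(np.std(all_scores)) / rmse
    return FitResult(
        params=params,
        residuals=res,
        rmse=rmse,
        fit_quality=fq,
        converged=bool(any_ok),
        n_obs=n_total,
        cost=float(best.cost),
    )


def fit(
    observations,
    timeline,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int | None = 0,
    max_nfev: int | None = None,
) -> FitResult:
    """Fit the model to one participant's ``(time_h, score)`` observations."""
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise InputError("observations must be an (n, 2) array of (time, score)")
    return _fit_datasets(
        [(obs[:, 0], obs[:, 1], timeline)],
        bounds=bounds,
        n_starts=n_starts,
        seed=seed,
        max_nfev=max_nfev,
    )


def fit_group(datasets, **kwargs) -> FitResult:
    """Fit a single shared parameter vector over several participants.

    ``datasets`` is a sequence of ``(times, scores, timeline)`` triples; the
    shared initial reservoir states apply at each participant's own timeline
    start and residuals are pooled.
    """
    return _fit_datasets(list(datasets), **kwargs)


@dataclass
class CVIteration:
    held_out: object
    train_fit_quality: float
    test_fit_quality: float
    test_rmse: float
    result: FitResult


@dataclass
class CVSummary:
    iterations: list[CVIteration] = field(default_factory=list)
    pooled_fit_quality: float = float("nan")


def cross_validate_group(datasets: Mapping[object, tuple], n_iter: int = 3, seed: int = 0, **fit_kwargs) -> CVSummary:
    """Leave-one-participant-out cross-validation of the group model.

    Each iteration fits on all-but-one randomly chosen participant and
    evaluates on the held-out participant's own timeline.
    """
    pids = list(datasets)
    if len(pids) < 3:
        raise InputError("group cross-validation needs at least 3 participants")
    rng = np.random.default_rng(seed)
    held = rng.choice(len(pids), size=min(n_iter, len(pids)), replace=False)
    summary = CVSummary()
    ho_obs, ho_pred = [], []
    for h in held:
        pid = pids[h]
        train = [datasets[p] for p in pids if p != pid]
        res = fit_group(train, **fit_kwargs)
        t, s, tl = datasets[pid]
        pred = predict(res.params, tl, t)
        summary.iterations.append(
            CVIteration(
                held_out=pid,
                train_fit_quality=res.fit_quality,
                test_fit_quality=fit_quality(s, pred),
                test_rmse=float(np.sqrt(np.mean((np.asarray(s) - pred) ** 2))),
                result=res,
            )
        )
        ho_obs.append(np.asarray(s, dtype=float))
        ho_pred.append(pred)
    summary.pooled_fit_quality = fit_quality(np.concatenate(ho_obs), np.concatenate(ho_pred))
    return summary


def cross_validate_individual(times, scores, timeline, n_iter: int = 3, seed: int = 0, **fit_kwargs) -> CVSummary:
    """Leave-one-day-out cross-validation of an individual model."""
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    days = np.unique(np.floor(times / 24.0).astype(int))
    if days.size < 4:
        raise InputError("individual cross-validation needs at least 4 distinct days")
    rng = np.random.default_rng(seed)
    held = rng.choice(days, size=min(n_iter, days.size), replace=False)
    summary = CVSummary()
    ho_obs, ho_pred = [], []
    for day in held:
        mask = np.floor(times / 24.0).astype(int) == day
        res = _fit_datasets([(times[~mask], scores[~mask], timeline)], **fit_kwargs)
        pred = predict(res.params, timeline, times[mask])
        tq = fit_quality(scores[mask], pred) if mask.sum() >= 2 else float("nan")
        summary.iterations.append(
            CVIteration(
                held_out=int(day),
                train_fit_quality=res.fit_quality,
                test_fit_quality=tq,
                test_rmse=float(np.sqrt(np.mean((scores[mask] - pred) ** 2))),
                result=res,
            )
        )
        ho_obs.append(scores[mask])
        ho_pred.append(pred)
    summary.pooled_fit_quality = fit_quality(np.concatenate(ho_obs), np.concatenate(ho_pred))
    return summary


class UnifiedPerformanceModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the modified unified model.

    Parameters
    ----------
    timeline : SleepWakeTimeline
        Cleaned alternating wake/sleep intervals (hours since origin); the
        sleep record is the independent variable of the model, so it is a
        constructor parameter rather than part of ``X``.
    bounds : mapping, optional
        Per-parameter ``(low, high)`` overrides of :data:`DEFAULT_BOUNDS`.
    n_starts : int
        Number of Latin-hypercube multi-starts for the bounded least-squares
        optimisation (the circadian offset makes the problem multimodal).
    random_state : int
        Seed for the multi-start sampler.

    Attributes
    ----------
    params_ : UMPParams
    result_ : FitResult
    rmse_, fit_quality_, converged_, n_obs_
    """

    def __init__(self, timeline=None, bounds=None, n_starts: int = 8,
                 random_state: int = 0, max_nfev: int | None = None):
        self.timeline = timeline
        self.bounds = bounds
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_nfev = max_nfev

    def fit(self, X, y):
        if self.timeline is None:
            raise InputError("a timeline must be supplied to fit the model")
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        res = _fit_datasets(
            [(t, y, self.timeline)],
            bounds=self.bounds,
            n_starts=self.n_starts,
            seed=self.random_state,
            max_nfev=self.max_nfev,
        )
        self.result_ = res
        self.params_ = res.params
        self.rmse_ = res.rmse
        self.fit_quality_ = res.fit_quality
        self.converged_ = res.converged
        self.n_obs_ = res.n_obs
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return predict(self.params_, self.timeline, t)
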