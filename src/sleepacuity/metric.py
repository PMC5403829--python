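"""Mental-acuity metric construction.

The 0-100 mental acuity score is an equally weighted linear combination of a
small feature set selected from the session feature battery:

    MA = sum_i (100/n) * T_i(x_i)

where percentage features enter through ``T(x) = x/100`` and unbounded
spread features (SDs of response times) through the reciprocal transform
``T(x) = 2*lambda / x``, with ``lambda`` the rate of a Poisson fit to the
observed feature distribution.  The published selection — logical-reasoning
percent correct, PVT SD in CRT (2*lambda = 200 ms) and 1-Back SD in CRT
(2*lambda = 600 ms) — is available as :func:`reference_definition`; each of
its three terms contributes 100/3 at nominal performance, so the score is
exactly 100 at (100 %, 200 ms, 600 ms).

Feature selection proceeds in two stages.  First, features that depend on
the absolute RT scale (means and medians of RT/CRT) are dropped because they
vary across phone hardware, and one of every highly collinear pair is
removed.  Second, an exhaustive wrapper fits a cross-validated linear
regression of prior-night sleep duration on every non-empty feature subset
and ranks subsets by the Bayesian information criterion
``BIC = n ln(RSS/n) + k ln(n)`` (small negative values are legitimate); the
final set is the lowest-BIC subset spanning at least three assessments and
containing at least one PVT feature.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from .errors import InputError, InsufficientDataError, SelectionError

__all__ = [
    "MetricDefinition",
    "reference_definition",
    "prune_features",
    "bic",
    "wrapper_search",
    "WrapperResult",
    "ExhaustiveBICSelector",
    "select_final",
    "poisson_scale",
    "mental_acuity",
    "SPREAD_FLOOR_MS",
]

#: Spread features are floored at one 60 Hz frame before the reciprocal.
SPREAD_FLOOR_MS = 1000.0 / 60.0

_ABSOLUTE_RT_STATS = ("rt_mean", "rt_median", "crt_mean", "crt_median")


@dataclass
class MetricDefinition:
    """A selected feature set with transforms and equal weights.

    ``transforms`` maps each feature to ``"percentage"`` or
    ``"reciprocal_spread"``; ``two_lambda`` holds the 2*lambda scale (ms) for
    each spread feature.  The weight is ``100/n`` for every feature.
    """

    features: tuple[str, ...]
    transforms: dict[str, str]
    two_lambda: dict[str, float] = field(default_factory=dict)
    per_term_cap: bool = False

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        for f in self.features:
            if f not in self.transforms:
                raise InputError(f"no transform for feature {f!r}")
            if self.transforms[f] == "reciprocal_spread" and f not in self.two_lambda:
                raise InputError(f"no 2-lambda scale for spread feature {f!r}")

    @property
    def weight(self) -> float:
        return 100.0 / len(self.features)

    def assessments(self) -> set[str]:
        return {f.split(".")[0] for f in self.features}

    def is_compliant(self, min_assessments: int = 3, required_prefixes=("pvt",)) -> bool:
        if len(self.assessments()) < min_assessments:
            return False
        return all(any(f.startswith(p + ".") for f in self.features) for p in required_prefixes)

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "transforms": dict(self.transforms),
            "two_lambda": dict(self.two_lambda),
            "weight": self.weight,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetricDefinition":
        return cls(
            features=tuple(d["features"]),
            transforms=dict(d["transforms"]),
            two_lambda={k: float(v) for k, v in d.get("two_lambda", {}).items()},
        )


def reference_definition() -> MetricDefinition:
    """The published three-feature mental-acuity metric."""
    return MetricDefinition(
        features=(
            "logical_reasoning.correct_pct",
            "pvt.crt_sd",
            "one_back.crt_sd",
        ),
        transforms={
            "logical_reasoning.correct_pct": "percentage",
            "pvt.crt_sd": "reciprocal_spread",
            "one_back.crt_sd": "reciprocal_spread",
        },
        two_lambda={"pvt.crt_sd": 200.0, "one_back.crt_sd": 600.0},
    )


def _feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if "." in c]


def prune_features(matrix: pd.DataFrame, correlation_threshold: float = 0.9) -> pd.DataFrame:
    """Drop absolute-RT features, then one of each highly correlated pair.

    Means and medians of RT/CRT are removed because they shift with phone
    hardware; SDs, percentages and counts survive that stage.  Then for each
    pair with ``|r| > correlation_threshold`` the later-listed column is
    removed.  Non-feature bookkeeping columns pass through untouched.
    """
    cols = _feature_columns(matrix)
    if len(cols) < 2:
        raise InputError("prune_features needs a matrix with at least 2 feature columns")
    keep = [c for c in cols if c.split(".", 1)[1] not in _ABSOLUTE_RT_STATS]
    corr = matrix[keep].corr()
    dropped: set[str] = set()
    for i, a in enumerate(keep):
        if a in dropped:
            continue
        for b in keep[i + 1:]:
            if b in dropped:
                continue
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > correlation_threshold:
                dropped.add(b)
    final = [c for c in keep if c not in dropped]
    passthrough = [c for c in matrix.columns if c not in cols]
    return matrix[final + passthrough]


def bic(n: int, rss: float, k: int) -> float:
    """Gaussian-likelihood BIC up to an additive constant: n ln(RSS/n) + k ln n."""
    if n <= 0:
        raise InputError("n must be positive")
    if rss < 0:
        raise InputError("rss must be non-negative")
    if rss == 0:
        warnings.warn("zero residual sum of squares; BIC is -inf", RuntimeWarning)
        return float("-inf")
    return n * np.log(rss / n) + k * np.log(n)


@dataclass
class WrapperResult:
    features: tuple[str, ...]
    bic: float
    cv_rmse: float


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(X)), X])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r)


class ExhaustiveBICSelector(BaseEstimator):
    """Exhaustive wrapper feature selection ranked by BIC.

    Fits an ordinary least-squares regression of the target (prior-night
    sleep duration) on every non-empty subset of candidate features, records
    the full-data BIC (``k`` = features + intercept) and the k-fold
    cross-validated RMSE, and ranks subsets by ascending BIC.  Enumeration is
    refused above ``max_columns`` candidates — prune first.

    Attributes
    ----------
    ranking_ : list[WrapperResult]
    best_ : WrapperResult
    """

    def __init__(self, cv_folds: int = 5, seed: int = 0, max_columns: int = 20):
        self.cv_folds = cv_folds
        self.seed = seed
        self.max_columns = max_columns

    def fit(self, X: pd.DataFrame, y):
        cols = _feature_columns(X) or list(X.columns)
        if len(cols) > self.max_columns:
            raise InputError(
                f"{len(cols)} candidate columns exceed the enumeration guard of "
                f"{self.max_columns}; run prune_features first"
            )
        y = np.asarray(y, dtype=float)
        data = X[cols].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.all(np.isfinite(data), axis=1)
        data, y = data[ok], y[ok]
        n = len(y)
        if n <= self.cv_folds:
            raise InsufficientDataError("too few complete rows for cross-validation")
        kf = KFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
        folds = list(kf.split(data))  # fixed fold assignment shared by all subsets
        results: list[WrapperResult] = []
        for size in range(1, len(cols) + 1):
            for subset in itertools.combinations(range(len(cols)), size):
                Xs = data[:, subset]
                rss = _ols_rss(Xs, y)
                b = bic(n, rss, len(subset) + 1)
                sq = 0.0
                for tr, te in folds:
                    A = np.column_stack([np.ones(len(tr)), Xs[tr]])
                    coef, _, _, _ = np.linalg.lstsq(A, y[tr], rcond=None)
                    At = np.column_stack([np.ones(len(te)), Xs[te]])
                    sq += float(np.sum((y[te] - At @ coef) ** 2))
                results.append(
                    WrapperResult(
                        features=tuple(cols[i] for i in subset),
                        bic=b,
                        cv_rmse=float(np.sqrt(sq / n)),
                    )
                )
        results.sort(key=lambda r: (r.bic, r.features))
        self.ranking_ = results
        self.best_ = results[0]
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        return self

    def get_support(self):
        best = set(self.best_.features)
        return np.array([c in best for c in self.feature_names_in_])

    def transform(self, X: pd.DataFrame):
        return X[list(self.best_.features)]


def wrapper_search(
    matrix: pd.DataFrame,
    target,
    cv_folds: int = 5,
    seed: int = 0,
    max_columns: int = 20,
) -> list[WrapperResult]:
    """Rank every non-empty feature subset by BIC (see ExhaustiveBICSelector)."""
    sel = ExhaustiveBICSelector(cv_folds=cv_folds, seed=seed, max_columns=max_columns)
    sel.fit(matrix, target)
    return sel.ranking_


def poisson_scale(values) -> float:
    """Twice the Poisson-MLE rate of the (integer-rounded) observations.

    The MLE of a Poisson rate is the sample mean, so this returns
    ``2 * mean(round(values))`` — the scale applied to unbounded spread
    features so a nominal observation maps to a full term share.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise InsufficientDataError("poisson_scale needs at least 10 observations")
    if np.any(x <= 0):
        raise InputError("poisson_scale requires positive values")
    return 2.0 * float(np.mean(np.rint(x)))


def select_final(
    ranked: Sequence[WrapperResult],
    matrix: pd.DataFrame | None = None,
    min_assessments: int = 3,
    required_prefixes: tuple[str, ...] = ("pvt",),
    two_lambda: Mapping[str, float] | None = None,
) -> MetricDefinition:
    """First ranked subset meeting the breadth constraints, as a metric.

    Percentage features get the ``x/100`` transform; SD features get the
    ``2*lambda/x`` transform with lambda estimated from the observed feature
    distribution in ``matrix`` (or taken from ``two_lambda`` when supplied).
    """
    if not ranked:
        raise SelectionError("empty ranking")
    two_lambda = dict(two_lambda or {})
    best_violators = []
    for res in ranked:
        transforms: dict[str, str] = {}
        tl: dict[str, float] = {}
        usable = True
        for f in res.features:
            stat = f.split(".", 1)[1] if "." in f else f
            if stat.endswith("_pct"):
                transforms[f] = "percentage"
            elif stat.endswith("_sd"):
                transforms[f] = "reciprocal_spread"
                if f in two_lambda:
                    tl[f] = float(two_lambda[f])
                elif matrix is not None and f in matrix:
                    tl[f] = poisson_scale(matrix[f].dropna())
                else:
                    usable = False
            else:
                transforms[f] = "percentage" if stat.endswith("pct") else "count"
        if any(t == "count" for t in transforms.values()) or not usable:
            # counts have no printed transform; treat subsets containing them
            # as non-compliant rather than inventing a scale
            best_violators.append(res.features)
            continue
        md = MetricDefinition(features=res.features, transforms=transforms, two_lambda=tl)
        if md.is_compliant(min_assessments, required_prefixes):
            return md
        best_violators.append(res.features)
    raise SelectionError(
        "no subset satisfies the selection constraints; best violators: "
        + "; ".join(map(str, best_violators[:5]))
    )


def mental_acuity(features: Mapping[str, float] | pd.Series, definition: MetricDefinition) -> float:
    """Evaluate the mental-acuity score for one session.

    Missing or invalid (NaN) features contribute 0, so a session with no
    responses scores 0; spread features are floored at one display frame
    (16.7 ms) before the reciprocal to avoid division blow-up.  Scores above
    100 are possible when a spread falls below its 2*lambda scale.
    """
    w = definition.weight
    score = 0.0
    for f in definition.features:
        x = features.get(f, float("nan")) if hasattr(features, "get") else features[f]
        x = float(x) if x is not None else float("nan")
        if not np.isfinite(x):
            continue
        kind = definition.transforms[f]
        if kind == "percentage":
            term = x / 100.0
        elif kind == "reciprocal_spread":
            term = definition.two_lambda[f] / max(x, SPREAD_FLOOR_MS)
        else:  # pragma: no cover - constructor forbids unknown transforms
            raise InputError(f"unknown transform {kind!r}")
        if definition.per_term_cap:
            term = min(term, 2.0)
        score += w * term
    return score
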