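# Methods

This note documents the models, conventions and numerical choices behind
`sleepacuity`, and what the synthetic cohort does and does not emulate.

## The performance model

Mental acuity is modelled as

MA(t) = v + β·[0.97·sin(2π(t − t_w + φ)/τ)] + α·S(t),

a circadian sinusoid anchored to the most recent wake-up time t_w plus a
homeostatic sleep-pressure process S.  S relaxes toward the reservoir
capacity U during wake (time constant τ_w = 10 h) and discharges during
sleep (τ_s = 2 h) toward a slowly moving lower reservoir L, which itself
relaxes toward U across wake periods and toward −2U across sleep periods
(τ_LA = 166 h).  All three time constants and the 0.97 circadian amplitude
are fixed; v, β, τ, φ, α and the initial states S₀, U, L₀ are free.

Both branches of S and both branches of the L₀ update are exact solutions
of their first-order ODEs.  We rely on this deliberately: the sleep-branch
coupling coefficient is written (L₀ + 2U)·τ_LA/(τ_LA − τ_s), the unique
form for which propagating (S, L) to any split point and restarting the
closed form reproduces direct evaluation ("semigroup" property).  That
two-route agreement, checked to 1e-9 over random parameters and split
points, is the implementation's correctness oracle — a typo in either
branch breaks it at the first transition.  One printed source form with a
minus sign in that coefficient is not semigroup-consistent and was read as
a sign typo.

Conventions:

- t, t_w, t₀ are fractional hours from the first midnight at or before the
  earliest record, so phases remain interpretable as clock hours.
- S₀ chains across intervals: the terminal homeostatic value of each
  interval seeds the next, and only the initial S₀ is fitted.  The α·S term
  is therefore continuous everywhere; the full prediction can still jump at
  wake onsets because the circadian anchor t_w resets there.  This
  discontinuity is a property of the model, not suppressed.
- During sleep, t_w is the start of the most recent wake interval.
- Restless minutes stay inside the sleep interval; the model branches at
  interval, not minute, granularity.

### Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, method
"trf") over the eight free parameters, τ ∈ [20, 28] h, φ ∈ [0, 28] h,
others broad.  The likelihood is multimodal in φ, so we run 8 seeded
Latin-hypercube multi-starts (v initialized at the observation mean, τ at
24 h in the first start) and keep the lowest residual sum of squares.  α
and the reservoir scale (U, S₀, L₀) trade off against each other; the fit
is reported in terms of predictions and fit quality, which are identified.

Fit quality = SD(observations)/RMSE(predictions) with the population
(divide-by-n) SD, so a constant predictor at the mean scores exactly 1.
Group models fit one shared parameter vector across participants, with the
shared initial states applied at each participant's own timeline start and
residuals pooled.  Cross-validation follows the study design: three
iterations holding out a random participant (group) or a random day's
sessions (individual).  Headline per-participant fit quality is computed on
the full fit, with cross-validated values reported alongside.

## Sleep-record cleaning

Tracker heart-rate dropouts fragment real nights into multiple events.
Adjacent events are merged when the gap is < 1.5 h, or < 3 h with
heart-rate present in fewer than 85% of the gap minutes; merging cascades
left to right so chains of fragments collapse, and a second pass is a
no-op.  Gap minutes with recorded steps are booked as awake, the rest as
asleep, conserving minutes.  All gap minutes count equally toward the 85%
coverage clause (restless minutes are not distinguished).  A "main sleep
event" is any cleaned event ≥ 3 h (configurable); wear compliance allows
0.5 h/day off wrist (a 1.75 h weekly charge plus 15 min daily bathing =
3.5 h per week), and participants are excluded when records are absent,
heart-rate coverage falls below 50%, or a worn device logs ≥ 3 consecutive
days without sleep events.

## Cognitive features

Per assessment and session: RT mean/median/SD (timeouts excluded), the same
for correct responses (CRT), correct/incorrect/timeout counts, percent
correct, and correct responses per minute of session (first stimulus to
last response — the standard per-minute convention, since the source lists
"rate" without definition).  PVT specifics: a lapse is an RT strictly
greater than 500 ms; a distracted answer is strictly greater than 1,250 ms
and is excluded from RT/CRT statistics but still counted as a lapse (the
thresholds nest); a misfire (response before stimulus) is excluded from
statistics; PVT "incorrect" = timeout or misfire.  Features require more
than five answered questions (misfires count as answers); non-PVT timeouts
come only from the log's timeout marker, never from an RT threshold,
because the app's allotted time is not part of the data contract.

Training effects are modelled as y(s) = c + a·2^(−s/h) over session index
s, fitted by bounded least squares; flat series are flagged as
unidentifiable.  The number of sessions to discard is the smallest whole
number strictly greater than the largest half-life — 3 for the reference
half-lives {0.67, 1.5, 2.6}.

Device QC: Kruskal–Wallis omnibus plus pairwise tests of PVT RTs by phone
model, and frame-clock discretization detection.  For the latter, the
autocorrelation of 8.33 ms histogram bin counts establishes whether a
periodic occupied-bin pattern exists (peak at least twice the background
autocorrelation and above 0.25); the spacing is then refined as the median
gap between adjacent occupied RT positions, since the frame period need not
be an integer number of bins (11.1 ms at 90 Hz under 8.33 ms bins).

## The mental-acuity metric

Score = Σ (100/n)·T_i(x_i) over the selected features, with T(x) = x/100
for percentages and T(x) = 2λ/x for unbounded spread features, λ the
maximum-likelihood Poisson rate of the observed (integer-rounded) feature
values.  The published selection — logical-reasoning percent correct, PVT
SD in CRT (2λ = 200 ms), 1-Back SD in CRT (2λ = 600 ms) — is built in as
`reference_definition()`; the score is exactly 100 at (100%, 200 ms,
600 ms) and 0 when no assessment has responses.  Spreads are floored at one
60 Hz frame (16.7 ms) before the reciprocal; scores above 100 are possible
(spread below 2λ) and no per-term cap is applied by default.

Selection: absolute-RT features (RT/CRT means and medians) are dropped as
device-dependent; of each feature pair with |Pearson r| > 0.9 the
later-listed column is dropped.  The exhaustive wrapper fits OLS of
prior-night minutes asleep (the most recent main sleep interval before each
session) on every non-empty subset, ranks by BIC = n·ln(RSS/n) + k·ln(n)
computed on the full-data residuals (k = features + intercept; small
negative values are legitimate), reports 5-fold cross-validated RMSE
alongside, and returns the lowest-BIC subset spanning ≥ 3 assessments with
≥ 1 PVT feature.  Enumeration is refused above 20 candidates.  BIC
consistency is asymptotic: the ln(n) penalty must dominate the χ²
fluctuation a decoy feature can absorb, so planted-subset recovery is
exercised at n = 2000 sessions where recovery exceeds 95%; at a few dozen
sessions the wrapper legitimately admits occasional extra features.

## Synthetic cohort

The generator emulates a 1-week free-living study: 24 participants, 3
sessions/day in 9–12 / 13–17 / 17–21 windows, bedtime ~23.5 ± 0.5 h,
nightly sleep ~N(7.3, 0.64²) h truncated to [2, 12] h, ground-truth acuity
following the performance model with per-participant parameters drawn
uniformly (v 60–80, β 6–14, τ 23.7–24.3 h, φ 0–24 h, α −1.4…−0.6 — negative
so acuity is highest soon after waking — U 6–14, S₀ 0–8, L₀ 2–10), and
additive N(0, 5²) session noise.  Realism knobs: per-device frame
quantization (ceil to the next frame boundary plus a latency offset) and
latency mix, 0.5%/min heart-rate dropout, off-wrist charge/bathing blocks,
15% sleep-event fragmentation with gaps < 1.5 h, per-assessment training
decay (amplitude 0.2; half-lives 0.67/1.5/2.6 sessions), and optional
session skipping (default full compliance).  One RNG per run, with
per-participant substreams derived from the seed, makes regeneration
deterministic.

Sessions are built by inverting the metric: the session's (noisy) target
score is split across the three metric terms in equal shares *subject to
per-term feasibility*, and responses are constructed to hit the resulting
feature targets exactly — correct counts are exact, and response times are
a symmetric two-point pattern affinely standardized to the target mean/SD.
Feasibility matters because PVT responses above 1,250 ms are excluded from
CRT statistics, so a valid PVT block cannot have a CRT SD above ~580 ms;
when the equal share would demand more, the PVT term is floored at its
feasible minimum and the deficit is redistributed to the other terms, and
at very low scores whole assessments are emitted as timeout-only (the
scale's "no responses" floor).  With zero noise, no training effect and no
quantization, simulate → extract → score therefore returns the target
within percent-correct granularity (< 1 point at 40 questions); this fixed
point is the generator's oracle.

What the generator does **not** emulate: lognormal RT marginals (two-point
spread patterns are used for exactness; only SD-based features feed the
metric), PPG waveforms and sleep staging, restless-minute microstructure,
nap behaviour, caffeine, and device clock drift.  Passing tests demonstrate
correctness of the analysis machinery under the model's own assumptions,
not validity of the model for any real cohort.

## Problem sizes and tolerances

Semigroup oracle: 10,000 random draws, tolerance 1e-9.  Individual-vs-group
comparison: 5 cohort seeds × 24 participants × 18 usable sessions, asserting
median individual fit quality > 1 and individual > group for ≥ 80% of
participants.  Wrapper recovery: 100 replicates at n = 2000.  Training-effect
recovery: half-life within 15% under 10% multiplicative noise pooled over 24
series.  Quantization congruence and metric monotonicity run as derandomized
property tests.  Noiseless fits must reproduce their observations to RMSE
< 1e-6; noisy fits to within 1.5× the injected noise SD.

## Known limitations

- The wrapper's BIC uses the Gaussian profile form up to an additive
  constant; absolute values are not comparable across targets with
  different units.
- α/U/S₀/L₀ are only jointly identified through α·S; reported parameter
  values are not individually interpretable.
- The merge rule consults heart-rate coverage only between events, not
  inside them; severely corrupted nights are handled by exclusion flags
  rather than repair.
- Group models assume a shared initial reservoir state at each
  participant's origin, which is an approximation when participants start
  recording at different circadian phases.
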