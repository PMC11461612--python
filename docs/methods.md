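# Methods

This note documents the models and procedures implemented in
`waitcast`, the choices made where the design was genuinely open, and
what the synthetic clinic does and does not establish about real data.

## Episode reconstruction

A visit's timeline is anchored on three HIS events: queue entry (T1),
the physician's call (T2), and the physician's *next* call in the same
session (T3). Waiting time is T2 − T1; consultation time is T3 − T2,
which therefore includes any idle gap before the next call — the
operational quantity a queue actually experiences, not the face-to-face
time alone. Choices:

- **Session boundary.** Calls before 12:30 are morning, later calls
  afternoon, and T3 chaining never crosses the boundary; otherwise the
  lunch break would be booked as the last morning patient's
  consultation. The last call of each physician-session has no T3: it
  contributes a waiting time but no consultation duration.
- **Ties.** Same-second events are ordered by the log's `Sequence`
  column, then file order.
- **Incomplete visits** (no queue entry or no call yet) are excluded
  and counted in a drop report, never silently discarded.
- Timestamps are naive local clinic time at second resolution.
- Appointment status and patient type ride along as log annotations
  (extra columns in the synthetic dialect); deriving them from medical
  records is out of scope.

## The synthetic clinic

Real HIS data is private, so a discrete-event simulator supplies logs
with the structure the framework assumes. Per physician and day:
patients arrive by a non-homogeneous Poisson process (piecewise-
constant hourly intensities; the defaults ramp upward within each
session, emulating the observed intensification of front-desk intake),
register from 08:00, and enter the queue immediately if they hold an
appointment (probability 0.909 by default) or after an exponential
delay (mean 10 min) if they walk in — appointment priority realized
exactly as a queue-entry delay, not a priority discipline. A fraction
(0.10) first takes a preliminary examination. The physician serves the
queue strictly FIFO during 09:00–12:00 and 13:00–17:30, running
overtime after the afternoon window until the queue clears.

- **Service times** are log-normal (mean 4.7, sd 2.7 minutes),
  truncated by resampling; the truncation cap of 15 minutes is applied
  jointly to service + idle gap, so the *reconstructed* gap between
  back-to-back calls respects the cap exactly. When the queue
  momentarily empties, the gap to the next call additionally contains
  pure waiting-for-arrivals time and can exceed the cap (≈0.7% of gaps
  at the default configuration); this is a property of measuring
  consultations from call chains, not a truncation failure.
- **Patient types** (returning / newly visiting / first-time /
  department-first-time) are i.i.d. per visit with probabilities
  proportional to 0.86 / 0.012 / 0.03 / 0.043, normalized to sum to 1.
- **Defaults** were chosen once to produce a congested clinic
  comparable in magnitude to a busy real department — mean waiting
  around 35–40 minutes, mean consultations ≈ 5 minutes, queues up to
  ~20–30 patients, ≈ 91% appointments. Reproducing any specific
  department's descriptive statistics exactly is a non-goal.
- **Reproducibility.** One root seed; per physician-day substreams are
  spawned deterministically, so identical configs give byte-identical
  logs.

What the simulator does *not* model: no-shows, physician breaks beyond
the idle-gap distribution, within-day correlation of patient types,
multi-department routing, or strategic behavior. Passing tests on
synthetic data therefore demonstrate the *pipeline's* correctness and
the qualitative loss/selection trade-offs, not calibrated performance
on any real clinic.

## Features

All nine predictors are anchored at the episode's **registration
time** (the earliest consistently logged event) and use only
information observable then:

| feature | meaning | units / default |
|---|---|---|
| `Q_L` | queue length of the assigned physician | patients |
| `Q_R`,`Q_N`,`Q_F`,`Q_D` | queue composition by patient type | proportions, partition of the queue |
| `A_S` | appointment made | 0/1 |
| `T_S` | registration in a smooth-flow zone | 0/1; zones [08:00,10:00) and [13:00,15:00) |
| `P_ACT` | mean duration of the physician's consultations that *ended* in the last τ minutes | minutes; 0 when none |
| `P_NP` | count of those consultations | patients; τ = 60 min |

Conventions: queue membership is the half-open interval [T1, T2) — a
patient called exactly at the anchor is no longer waiting; the arriving
patient is excluded from their own snapshot; a consultation straddling
the anchor contributes nothing to `P_ACT`/`P_NP` (only completed
durations are knowable); queue members without a patient-type label
raise an error rather than skewing the ratios.

## Preprocessing

Fixed order: physician-stratified 80/20 split → square-root transform
of waiting minutes (right-skew reduction) → Tukey fences
(Q1 − 1.5·IQR, Q3 + 1.5·IQR, linear-interpolation quartiles) on the
*transformed* target, fitted on train and applied unchanged to test,
with boundary values kept → min-max scaling of the continuous features
with training bounds; binary flags pass through; test values outside
the training range are *not* clipped (clipping would corrupt
de-normalized narrative values). Features are never outlier-filtered.
The fitted state is a small JSON document sufficient to transform
unseen data identically and to de-normalize cited feature values.

## Asymmetric losses

With ε = y − ŷ (positive = underestimation):

- Quad-Quad: `L(ε) = 2[α + (1 − 2α)·1{ε<0}]ε²`, α ∈ (0, 1); α = 0.5 is
  exactly the squared error, α > 0.5 penalizes underestimation more.
- LINEX: `L(ε) = (2/β²)(e^{βε} − βε − 1)`, β ≠ 0; β → 0 recovers the
  squared error (the sup-norm deviation on a bounded interval is
  ≈ β|ε|³/3).

Derivatives are taken w.r.t. the prediction, the convention boosting
objectives consume: Quad-Quad d1 = −4cε, d2 = 4c with c the side
coefficient; LINEX d1 = −(2/β)(e^{βε} − 1), d2 = 2e^{βε}. Numerical
choices: the ε = 0 branch uses the underestimation coefficient (loss
and d1 are continuous there; fixing the branch makes hessians
deterministic); d2 is floored at 1e-6 so the degenerate α = 1.0 limit
(admitted but flagged) cannot stall second-order steps; the LINEX
exponent is capped at |βε| = 30 with linear continuation — far outside
the range reachable on a √minutes scale, but it keeps pathological
inputs finite and convex. **Losses act in the transformed (√minutes)
space** — the space the model predicts in; all *metrics* are computed
in minutes (below). Raw predictions are floored at 0 before squaring
back to minutes, since a negative √wait is meaningless.

## Metrics, DAES and selection

Predictions are inverse-transformed to minutes before any metric: the
printed-accuracy identity R² = 1 − (RMSE/sd)² only holds on the minute
scale, which fixes the evaluation space unambiguously. ε = 0 counts as
neither under- nor overestimation; empty conditional subsets score 0.

`DAES(γ) = ρ(ε>0)·RMSE(ε>0) + ρ(ε<−γ)·RMSE(ε<−γ)` with γ in minutes
(default 30). It is non-increasing in γ, and for a symmetric-loss
model the test report is invariant to γ entirely.

Selection runs repeated k-fold CV (default 5×5, seeds explicit) over a
candidate grid — symmetric squared error, Quad-Quad α ∈ {0.5…1.0},
LINEX β ∈ {0.1…1.0} — averaging fold-level metrics (fold-averaged and
pooled underestimation ratios are both reported, since the two differ
slightly). Exact score ties go to the candidate closest to its
family's symmetric member (least distortion). Hyperparameter search is
a pluggable seeded random-search contract; the default budget of 1
keeps the documented LightGBM defaults. The γ-sweep computes fold
predictions once per candidate and re-scores DAES per γ from them —
identical to re-running selection per γ, because the predictions do
not depend on γ.

## Shapley explanations

The value function is the **interventional** (background-substitution)
expectation: f_x(S) is the mean model output over background rows with
the coalition S's features replaced by x's values. This is the variant
the tree path computes exactly; under dependent features it differs
from the observational conditional expectation, and the choice is
deliberate — attributions answer "what did the model do with these
inputs", not "what would we infer from them".

Two routes, gated against each other in tests:

- **Exact enumeration** over all 2^M coalitions (M ≤ 15), all
  evaluations batched into a single model call.
- **Closed-form tree path**: for one background row z, each tree leaf
  is reached iff every path feature where only x satisfies the leaf's
  box is present (set P, size p) and every feature where only z
  satisfies it is absent (set N, size n); such a unanimity-style term
  has Shapley value `leaf·(p−1)!n!/(p+n)!` for members of P and
  `−leaf·p!(n−1)!/(p+n)!` for members of N. Summing over leaves and
  averaging over the background reproduces the exact values to
  machine precision, at cost linear in leaves × background.

The background defaults to the training split, capped at 500 rows by
seeded subsampling. Global importance is the mean |φ| per feature
(ties ranked alphabetically). The dependence "auto" interaction picker
bins the feature's values and scores each candidate by the within-bin
variance of φ it explains linearly — a documented heuristic standing
in for a full interaction decomposition.

**Narratives.** φ lives in the model's √minutes output space; only the
total prediction is converted to minutes, and per-feature effects are
described by direction only, because a nonlinear inverse transform
does not distribute over additive terms. Cited feature values are
de-normalized through the stored min-max bounds (counts to whole
patients, durations to 2 dp), and every number rendered in the text
equals the stored de-normalized value by construction.

## Problem sizes

The test suite and the acceptance script exercise the full pipeline on
the default synthetic clinic of 3 physicians × 20 days (~5,500 visits,
~4,400 training rows after the 80/20 split and outlier removal), with
5×5-fold cross-validation over the Quad-Quad α ladder; oracle
equivalences use small constructed models (≤ 5 features, ≤ 30 trees)
where brute-force enumeration is exact and cheap. These sizes were
chosen as the smallest at which the congestion regime and the
selection trade-offs are stable across seeds.

## Known limitations

- The simulator's arrival intensities are stationary across days; real
  clinics have weekday and seasonal structure the features would pick
  up.
- `P_ACT`/`P_NP` reset at the lunch break implicitly (no morning
  consultation ends within τ of an early-afternoon registration); real
  physicians carry momentum across sessions.
- The tree path supports numeric `<=` splits (LightGBM's default);
  categorical splits would need an adapter extension and currently
  fall back to exact enumeration.
- DAES with RMSE as base metric is scale-dependent; comparing scores
  across datasets with different waiting-time scales requires care.
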