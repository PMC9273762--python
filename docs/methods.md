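# Methods

## Problem

Hospital wards run mandated track-and-trigger observation charts: each vital
sign has coloured derangement zones, and a measurement in the red zone
raises a red-flag alert that escalates care. `wardflag` predicts, at the
moment a new observation lands in the record, whether **any** vital sign of
that patient will breach the red zone within the next W hours
(W ∈ {2, 4, 6, 8}). Predicting the alert — rather than death, arrest or ICU
transfer — keeps the target aligned with the protocol already in clinical
use and gives the response team lead time; it also sidesteps the
confounding that treatment triggered by the existing protocol introduces
into outcome-based labels.

## Data model

Inputs are a long-format observation stream (encounter, patient, timestamp,
vital, value) and an encounter table (admission/discharge, age, sex, care
type). Seven numeric vitals receive full feature treatment — systolic and
diastolic blood pressure, mean arterial pressure, heart rate, temperature,
respiratory rate, SpO2 — plus the AVPU consciousness scale
(Alert/Verbal/Pain/Unresponsive) and supplemental O2 flow, which enter only
as presence flags. Timestamps are handled at minute resolution and all
durations are minutes internally.

Screening drops rows outside per-vital plausibility ranges (closed
intervals, e.g. SBP [0, 300], TEMP [30, 42.2], SpO2 [50, 100]); AVPU is
categorical and never range-screened. Out-of-range values are dropped, not
truncated: a clearly impossible reading is more plausibly an entry error
than a saturated true value.

### Cohort and response

The cohort funnel keeps acute-care encounters, requires length of stay
≥ 24 h (window statistics such as an SD need a populated lookback),
requires at least one vital observation, and requires that the response be
computable (at least one observation of a vital the protocol covers).

Red-zone predicates are configuration, not data: charts differ between
institutions. The shipped defaults (RR < 5 or > 30, SpO2 < 90,
SBP < 90 or > 200, HR < 40 or > 140, TEMP < 35.5 or > 38.5, MAP < 60,
AVPU ∈ {Pain, Unresponsive}) are illustrative and fully overridable.

Prediction points are the observation timestamps themselves — the pipeline
is event-driven. A point at which a red flag is concurrently firing is
excluded (predicting an alert already raised is vacuous), and the label for
horizon W is 1 iff a flag falls in the half-open interval (t, t+W].
Intervals nest, so a 2-h positive is necessarily a 4/6/8-h positive. Points
after an encounter's first flag are retained by default
(`censor_after_first_flag` flips this): later deteriorations of the same
admission are still worth predicting.

### Features

82 columns per prediction point: for each of the seven aggregable vitals,
eleven statistics over the 24-h lookback (t−H, t] — min, max, mean, median,
population SD, frequency, number of distinct vitals measured at t, number
of observations in the window, last value, interval between the last two
observations, and the slope (y₂−y₁)/(t₂−t₁) of the last two, in units per
minute — plus O2-flow and AVPU presence flags, age, sex (male = 1), and
length of stay at t in minutes.

Numerical choices worth knowing:

* **frequency** is defined as n_in_window / H (observations per hour), a
  rate, so it stays distinct from the raw count when H is reconfigured;
  frequency × H = n_in_window holds exactly.
* **SD** uses the population formula and is 0 (not missing) for a single
  observation, which keeps missingness from spraying into tree training.
* **slope** is missing when fewer than two observations exist or when the
  last two share a timestamp — never a division failure.
* A vital unobserved in the window gets missing aggregates; trees route
  missing values through the branch learned at fit time (scikit-learn's
  native missing-value support), and explanation traverses the identical
  path, so prediction and attribution never disagree about routing.
* `n_at_current` (distinct vitals at t) has one underlying value but is
  replicated into each vital's block so the per-vital blocks stay uniform —
  that replication is what makes the 7 × 11 + 5 = 82 layout come out.

## The encounter-based forest

Ward feature tables are long panels: one admission contributes hundreds of
correlated rows, and sicker patients are observed more often, so a row-level
bootstrap over-samples exactly the rows that are least exchangeable. The
ensemble therefore bootstraps **encounters**:

1. *One point per encounter.* For each of the B sub-samples, every training
   encounter contributes exactly one prediction point, drawn with
   probability proportional to the inverse frequency of its label class
   within that encounter (an encounter containing both classes is equally
   likely to contribute either).
2. *Class balancing.* The one-per-encounter pool is resampled with
   replacement to its own size, half the draws from each class — the
   inverse-class-frequency weighting conditioned on exact balance, so every
   sub-sample is evenly split. Balancing can be disabled (`balance="off"`);
   a single-class pool degrades gracefully with a warning. A non-default
   `encounter_sampling="replacement"` mode bootstraps encounters themselves
   before the within-encounter draw, at the cost of an encounter appearing
   more than once in a sub-sample.
3. One depth-limited CART tree (Gini) per sub-sample; the ensemble
   probability is the arithmetic mean of per-tree leaf probabilities (no
   smoothing by default; Laplace-style shrinkage is available via
   `leaf_smoothing`).

Tree b uses seed base_seed + b, so any single member is reproducible in
isolation. B defaults to 1000; the bundled studies use 40–200, which is
where the ensemble mean has visibly stabilised at these cohort sizes.

Hyperparameters (max_depth, min_samples_leaf) are selected by fitting on
the chronologically earliest partition and maximising AUC-PRC on a later
validation partition — the appropriate criterion at 5–8% prevalence, where
AUC-ROC saturates. Ties break toward the simpler model (smaller depth,
then larger leaves).

### Evaluation

AUC-ROC uses the rank (Mann–Whitney) formulation with tie correction;
AUC-PRC uses step-wise, non-interpolated integration of the
precision–recall curve (linear interpolation is optimistically biased under
imbalance). Threshold metrics (precision, recall, NPV, F1) come from the
confusion matrix at p > 0.5 by default. Confidence intervals use R = 1000
bootstrap resamples drawn with replacement *within class*, so every
resample reproduces the test prevalence exactly; the default interval is
the Student-t construction mean ± t₀.₉₇₅,R₋₁·sd/√R, which quantifies the
precision of the bootstrap mean and is therefore very narrow — percentile
intervals (`method="percentile"`) are the right choice when coverage of an
underlying truth is the question, and the test suite checks coverage on
that construction. Covariate balance between partitions uses Welch t-tests
(continuous) and chi-square tests (categorical) with standardised mean
differences (pooled-SD form; Mahalanobis form for multi-level categories);
p-values are descriptive.

Baseline comparisons (lasso logistic regression, single decision tree,
random forest, XGBoost) are thin wrappers over the standard
implementations, trained on the *same* encounter-level sub-samples with the
same seeds and aggregated by probability averaging, so any difference from
the encounter forest is attributable to the learner, not the sampling.
The linear model gets a median-imputer + scaler pipeline since it cannot
consume the missing-value encoding trees handle natively.

### Risk index and calibration

The calibration curve bins predictions into 10 probability quantiles (ties
kept together; degenerate score distributions merge bins) and reports mean
predicted probability against observed event proportion with Wilson 95%
intervals. Predictions map to a three-level deterioration risk index with
strict thresholds: index 1 for p > 0.95, index 2 for 0.85 < p ≤ 0.95,
index 3 for 0.70 < p ≤ 0.85; boundaries fall to the lower-risk index, and
p ≤ 0.70 gets no index. The thresholds are fixed probabilities, not
empirical population quantiles (a quantile mode exists behind a flag); the
two coincide only when the score distribution happens to match. Per-index
precision and two recalls are reported: *within-group* recall is 1 by
construction for any non-empty group (no positive inside the group can be
missed by the group's own alert), while *vs-all-events* recall divides the
group's true positives by all positives in the test set — both are emitted
because summary tables in the field do not always say which denominator
they use.

## Shapley explanations

Each tree is explained with the polynomial-time path-dependent tree Shapley
algorithm; the value function is the conditional expectation obtained by
descending the tree, following x for coalition features and cover-weighted
averaging otherwise. Each tree's background is its own bootstrap
sub-sample — exactly the cover weights the fitted tree carries — so
explainer and model see the same data. The ensemble explanation is the
plain average of per-tree (φ, φ₀); because the ensemble prediction is the
average of tree outputs, local accuracy φ₀ + Σφ = f(x) holds at the
ensemble level by linearity, and the suite asserts it numerically.
Contributions are in probability units and directly readable as risk
percentage points. An exhaustive 2^M coalition-enumeration implementation
of the same value function ships alongside as an independent correctness
reference; the two agree to machine precision on random small trees,
including trees with missing-value routing.

Global importance is the population mean of |φ| per feature; per-patient
reports list the top-k contributors by |φ| (ties break by schema order)
with raw feature values attached for high/low colour-coding in the bundled
plots.

## The synthetic ward generator

Real ward extracts behind mandated protocols are not redistributable, so
the package ships a generator with known ground truth. What it emulates:

* **Marginals**: per-vital baselines use published ward cohort means/SDs
  (SBP 126.69/21.16 mmHg, SpO2 96.52/2.33%, …); age 59.9 ± 17.2 years, 62%
  male; length of stay lognormal matched to a cohort mean of ~13,470 min
  with an SD of ~27,830 min, truncated at 21 days (the package's default
  study scale; configurable). A small non-acute admixture (5%) and the
  natural short-stay tail exercise the cohort funnel.
* **Trajectories**: mean-reverting (Ornstein–Uhlenbeck, τ = 12 h) noise
  around a per-encounter baseline, sampled at per-vital exponential
  inter-arrival times (mean 8 h; halved for at-risk encounters, emulating
  denser observation of sicker patients), clipped to validity ranges.
* **Deterioration**: at-risk encounters (50%) carry a phenotype — e.g.
  respiratory failure (SpO2 −0.8 %/h, RR +1.5 /h) or a sepsis-like pattern
  (SBP −2.5, TEMP −0.06, HR −1.2 per hour) — with a per-hour onset hazard;
  after onset the driver vitals drift linearly for `episode_duration_h`
  (24 h) and then recover at the same rate, so red flags cluster around the
  trough rather than persisting to discharge, which is what makes the
  window prevalence tunable into the observed 5–8% band. AVPU grades from
  Alert through Verbal/Pain/Unresponsive with episode depth; O2 flow is
  present for 36% of encounters and titrates up during episodes.
* **Stable dispersion**: cohort SDs describe a mixture of stable and
  deteriorating physiology. A Gaussian stable phenotype with the full
  cohort SD would breach red thresholds several percent of the time from
  noise alone (SBP < 90 alone is ~4%), drowning the episode mechanism; the
  stable phenotype therefore uses 55% of the cohort SD, and with the
  default thresholds the stable red-flag rate is below 1% per observation.
* **Calibration**: `tune_prevalence` bisects a multiplicative hazard scale
  (prevalence is monotone in it) until the labelled event rate at the
  chosen horizon hits a target such as 8%, mirroring reported event rates
  of 5% at 2 h rising to 8% at 8 h.

What it does **not** emulate: interventions and their feedback on vitals,
medication effects, inter-hospital casemix, measurement error structure
beyond OU noise, or correlated multi-vital failure beyond the fixed
phenotype drifts. Passing tests on this generator demonstrates that the
pipeline recovers planted mechanisms and honours its contracts — not that
the clinical performance figures would transfer to any real ward.

## Reproducibility

Everything is seeded: the generator, every sub-sample (base seed + b), the
bootstrap CIs, and the pipeline's explanation sampling. `run_all` splits
encounters chronologically by admission (50/25/25 by default; study runs
here use 35/25/40 to enlarge the held-out period), never divides an
encounter across partitions, asserts on every run that no test-period
encounter reaches a training sub-sample, and writes a sha256 manifest of
its CSV outputs — rerunning with the same config and seed reproduces
identical digests.

## Default study conditions

The bundled tests and the acceptance script run at desk scale chosen as the
package's default study conditions: cohorts of 100–650 encounters,
B = 40–200 trees, hazard calibrated to ~8% prevalence at the 8-h horizon.
At those conditions the encounter forest reaches AUC-PRC ≈ 0.75–0.84
against a 0.06–0.08 no-skill baseline, AUC-ROC ≈ 0.96–0.98, monotone
risk-index precision (e.g. 0.96/0.75/0.33 at seed 1), and the global
Shapley importance recovers the planted SpO2/RR drivers in the top 5 of 82
features. These are properties of the synthetic mechanism, reported by the
code that computes them; they are qualitative analogues of, not substitutes
for, results on hospital data.

## Known limitations

* The generator's episodes are single, phenotype-pure and piecewise-linear;
  real deterioration is messier, and feature importance on real data will
  not be as clean as the planted-driver recovery here.
* Within-group recall of 1 is structural under the threshold construction,
  not evidence of sensitivity; the vs-all-events recall is the informative
  column.
* Probabilities from class-balanced training are shifted upward relative to
  the raw event rate; the risk index consumes them through fixed high
  thresholds, but anyone reading the probabilities as absolute risks should
  recalibrate (deliberately out of scope).
* The t-based bootstrap CIs are intervals for the bootstrap mean, not
  coverage intervals for the underlying metric; use the percentile option
  for the latter.
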