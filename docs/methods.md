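# Methods

This note documents the statistical procedures implemented in `painvol`,
the synthetic data-generating process used to validate them, and the design
choices made where the problem left the design genuinely open.

## The volatility statistic

For ordered severity ratings R = ⟨R₁, …, Rₙ⟩, pain volatility is

V(R) = Σᵢ₌₂ⁿ |Rᵢ − Rᵢ₋₁| / (n − 1),

the mean absolute successive difference.  Consecutive means consecutive in
record order, regardless of the elapsed time between reports — a deliberate
simplification that keeps the statistic well defined under the highly
irregular sampling of self-initiated app records.  The divisor is n − 1,
the number of successive gaps; it is the only divisor under which all four
canonical trajectories (V = 10, 4, 2, 0 for the big-changes, small-changes,
steady-upward and constant series) come out consistently.  V is
translation-invariant, scales linearly with the rating units and is bounded
by [0, 10] on an integer 0–10 scale.  A minimum of two ratings is required;
the eligibility filter demands five per window to keep the estimate
reliable.  The comparison statistic `compute_sd` is the sample SD
(divisor n − 1), which mis-ranks a steady trend above a small saw-tooth and
is retained only as a foil and a feature.

## Observation windows and eligibility

A "month" is a 30-day block anchored at the user's first record t₀, not a
calendar month, so window lengths are identical across users and V is
comparable.  Predictor window: [t₀, t₀+30 d); outcome window: [t₀+150 d,
t₀+180 d); both half-open so no record can be double-counted and a record
at exactly day 30 belongs to neither.  Eligibility = at least 5 records in
*both* windows and gender ≠ "other" (too few such users to support stable
per-class estimates).  Records are counted, not distinct days.  Note that
eligibility is monotone only under records appended at-or-after the
anchor: a record inserted *before* a user's first record moves t₀ and can
re-partition the windows.

## Threshold derivation

Each eligible user contributes two V scores (predictor and outcome
window).  The pooled scores are clustered by 1-D k-means with k = 2
(Lloyd's iterations).  Restarts are initialised both from the segment
means of sorted-order splits (every split for n ≤ 512, evenly thinned
above) and from random pairs of distinct data values; because a restart
started from a split's own means can only improve on that split's SSE,
covering the splits makes attaining the sorted-split optimum — the global
k = 2 optimum in 1-D — certain rather than merely likely, which matters on
weakly separated data where random restarts alone occasionally stall in a
local optimum.  The threshold is the midpoint between the largest
low-cluster value and the smallest high-cluster value.  Classification is
by strict inequality: a score exactly at the threshold is *low*.  If all
pooled scores are identical the clustering is degenerate and an error is
raised rather than an arbitrary threshold returned.

Stability is assessed by re-clustering 4 random half-size subsamples
(without replacement) and comparing their thresholds with the full-data
value; a spread below ±0.2 on a 0–10 scale is treated as stable.

Ambiguity note: final labels could equally have been read off the pooled
cluster assignment itself.  We apply the threshold to each window's score
instead, which keeps labelling a pure function of (score, threshold) and
lets new users be labelled without re-clustering.

## Feature extraction (130 features)

Per eligible user, from the profile plus predictor-window records only:

| block | features | notes |
|---|---|---|
| gender | 1 categorical | male / female / unknown (missing → unknown) |
| age group | 1 categorical | 8 bins: unknown, (0,20], (20,30], …, (60,70], >70; lower-exclusive, upper-inclusive |
| number of conditions | 1 categorical | unknown / 1 / 2 / 3 / >3; zero reported conditions → unknown |
| condition categories | 5 binary | fibromyalgia, headaches, back pain, arthritis, depression-anxiety |
| app usage | 2 counts | records in window; distinct active days |
| severity | 2 continuous + 1 categorical | mean, SD (divisor n−1, matching `compute_sd`); group mild (<4) / moderate (4–7 incl.) / severe (>7) |
| trend change | 1 continuous | OLS of severity on elapsed days; slope × window span; 0 if all timestamps equal |
| volatility | 1 continuous + 1 binary | window V; level = V > global threshold (no local re-clustering) |
| descriptors | 64 binary | presence of each of 24 locations, 20 symptoms, 13 characteristics, 7 environments anywhere in the window |
| factors | 43 binary | 15 aggravating, 14 alleviating, 14 ineffective |
| medications | 5 binary | opioids, tricyclics, anticonvulsants, cannabinoids, SNRIs; fire only when a categorised profile medication is attached to a record in the window |
| neuropathic pain | 1 binary | ≥ 2 of {pins-and-needles/tingling, burning, numbness, electric shocks (characteristics), light touch or clothing (aggravating)} in one single record |
| mental health | 1 binary | any record with anxiety/depression (symptom) or negative mood/stress (aggravating factor) |

The trend regressor is elapsed days rather than record index because
index-based slopes depend on sampling density.  Categorical features stay
single columns in the canonical schema (so the count is 130) and are
one-hot expanded only at model-fit time.  Missing profile information maps
to explicit *unknown* categories, never to errors, so the 130-column
identity holds for every user including the all-missing case.  Vocabulary
cardinalities are structural; the shipped token names are a synthetic
default standing in for an app's proprietary pick-lists and can be
replaced by configuration.

## Prediction protocol

Four model families: logistic regression with ridge (L2) penalty, logistic
regression with the LASSO (L1), Random Forests, RBF-kernel SVM.
Preprocessing (one-hot of categoricals, standardisation of non-binary
numeric columns) is fit on training folds only.  The logistic penalty
strength is chosen per training fold by internal stratified 10-fold CV
over a log-spaced grid with the one-standard-error rule (strongest penalty
within one SE of the best mean accuracy), the standard practice of the
penalised-regression toolchain this mirrors; standardisation is done once
on the training fold, as that toolchain does.  Random Forests uses 100
trees and mtry = round(2·√n) = 23 features per split for n = 130 canonical
features ("2·√n" is taken literally; it is configurable since it plausibly
rounds a different rule).  SVM uses library defaults (C = 1,
gamma = "scale"); no tuning is attempted, and the SVM's weaker performance
should be read with that in mind.

Evaluation is stratified 5-fold cross-validation: both classes are split
into five near-equal groups, each user is tested exactly once, and
per-fold class counts are within one member of an even split.  Three
measures are reported, with high volatility as the positive class:
acc_low = TN/(TN+FP), acc_high = TP/(TP+FN), acc_overall = (TP+TN)/N (all
×100%); acc_overall is algebraically the label-frequency-weighted mean of
the other two.

Class imbalance (roughly 4:1 low:high) is addressed by randomly
subsampling the majority class to the minority size *within each training
fold* — never the test fold, so test distributions stay intact and no
test information leaks into training.  The subsampling is repeated 3 times
with fresh draws while the CV folds stay fixed, isolating subsampling
variance from fold variance.

## The synthetic data-generating process

The generator emulates a pain-app export: a profiles file and a six-month
record stream per user, with ground-truth latent states for validation.

**Latent states.** A user's month-6 volatility state is high with
probability 171/782 ≈ 0.219 (the class mix the pipeline is designed
around).  The month-1 state equals the month-6 state with probability
0.5 + s·(p − 0.5), where p = `regime_persistence` (default 0.85) and
s = `signal_strength` (default 0.8).  Scaling the persistence by s makes
s = 0 a true null: month-1 volatility — itself an extracted feature — is
then independent of the outcome, along with everything else.

**Severity dynamics.** Ratings follow a discretised mean-reverting AR(1)
walk x' = μ + a·(x − μ) + σ·ε, emitted as clip(round(x'), 0, 10), with a
per-user baseline μ ∈ {3,…,7} and a 60-step burn-in so every month starts
in the stationary regime.  `calibrate_step_scale` bisects σ (AR
coefficient chosen from a ladder preferring weak persistence, which
concentrates month-level V most tightly; targets above ~5 are reachable
only with anti-persistent dynamics on a clipped scale) until a
100 000-step simulation realises the target mean absolute step within 5%.
Regime targets default to 0.8 (low) and 3.0 (high), placing the two
month-level V distributions on opposite sides of the mid-1 range with
>95% separation.  A target of 0 yields a constant path; 10 the degenerate
0/10 alternation (the only pattern attaining it); above 10 is
unattainable and raises an error.

**Records.** Record counts per user-month are Poisson with mean 12,
floored at 5 by default (the floor is a flag; the true count distribution
of real exports is unknown and this is a free choice).  Timestamps are
uniform over each 30-day block during waking hours; the first record
anchors t₀.  Descriptor/factor tokens are drawn from per-user preferred
subsets, emulating habitual reporting.  Missingness matches the reported
structure of such cohorts: 25% gender unknown, 31% age unknown, 2% of
users report no descriptors, 8% no factors.

**Planted signal.** Besides regime persistence, five designated tokens
(anxiety, depression symptoms; stress, negative-mood aggravating factors;
burning characteristic) appear in month 1 with probability 0.5 ± 0.3·s
depending on the month-6 state.  Four of the five drive the mental-health
flag, a clinically plausible correlate of volatile pain.

**What the generator does not model:** app-engagement decay and dropout,
calendar seasonality, autocorrelated reporting gaps, free-text condition
noise, and any real-world correlation structure among the 130 features.
Tests passing on synthetic cohorts therefore demonstrate that the
*pipeline* is correct and that the protocol behaves as designed (imbalance
pathology, its subsampling cure, chance-level accuracy under the null) —
they do not certify accuracy levels on real app data, whose signal
strength is unknown and surely weaker and messier.

## Numerical choices and degenerate inputs

- Volatility/SD require n ≥ 2 and raise otherwise; the empty predictor
  window is an upstream eligibility violation and raises.
- k-means raises on all-identical values instead of fabricating a split.
- Ties at the threshold classify as low (strict inequality for high).
- Trend change returns 0 for coincident timestamps (zero design span).
- Readers map unparseable gender/age to unknown but *reject* out-of-range
  severities, unknown vocabulary tokens, duplicate user ids and malformed
  rows, naming the offending line.
- Records sorting is by (user_id, timestamp) with stable ties preserving
  file order; a tie triggers a warning since same-instant ordering is
  ambiguous.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical (config, seed) reproduces
  byte-identical cohorts and experiment results.

## Problem sizes used in validation

The reproduction script (`scripts/acceptance.py`) uses a 782-user cohort,
matching the population size the pipeline targets, and runs all four
models in both balancing modes.  The test suite uses cohorts of 60–800
users (and 5000 for a binomial check of the outcome-state rate), chosen so
the statistical assertions have comfortable margins.

## Known limitations

- The delimiter dialect (pipe / semicolon) is this package's own; real
  exports would need a thin adapter.
- Condition and medication category mappings are fixture tables, not an
  NLP mapping of free text; real deployments must supply their own.
- The SVM is deliberately untuned; its accuracies characterise the default
  configuration, not the method's potential.
- Feature selection, probability calibration and AUROC-style metrics are
  out of scope; the three per-class accuracy measures are the interface.
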