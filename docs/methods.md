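# Methods

## The problem and the pipeline

Wrist wearables report heart rate as integer BPM about once per second. The
question this package addresses is whether that single, low-rate channel
carries enough information to distinguish a wearer's emotional state
(neutral, happy, sad) under a controlled 'neutral + target' stimulus design:
each session pairs a neutral video segment with a target-emotion segment,
and the neutral segment's mean heart rate serves as the subject's baseline.

The pipeline is:

1. **Segmentation** — split each session at the neutral/target boundary
   (half-open intervals; the boundary sample belongs to the target segment,
   so segment lengths sum to the session length).
2. **Baseline normalization** — subtract the neutral-segment mean from the
   target segment: `X~_i = X_i - mean(neutral)`. Resting heart rate varies
   far more between subjects (~±10 BPM) than emotion moves it within a
   subject (a few BPM), so between-subject variation must be removed before
   features can transfer across subjects.
3. **Feature extraction** — 53 features (22 from the original target
   segment, 31 from the normalized signal); see `FEATURES.md`.
4. **Selection** — rank features by estimated mutual information with the
   emotion label; keep the top k, k in {20, 16, 12, 10, 8, 5}.
5. **Evaluation** — five classifier families (kNN, random forest, decision
   tree, gradient boosting, AdaBoost) under leave-one-out cross-validation,
   for three pairwise tasks and the three-class task. Each (task,
   classifier, k) cell is evaluated ten times and reported as the mode of
   the ten accuracies.

## Run statistics

Because BPM values are integers, the signal moves in unit steps and
plateaus. A *run* is a maximal stretch over which consecutive differences
share a sign (+, -, 0). Runs tile the series — consecutive runs share their
boundary sample, and run durations sum to `(N-1)·dt`. Up/down-run durations
measure how long the heart rate keeps rising or falling, flat-run durations
measure plateau persistence, amplitudes measure excursion size, and
down-slopes (|amplitude|/duration) measure recovery speed. These are the
morphological features that distinguish a drifting from a volatile trace at
equal mean and variance.

## Numerical conventions

Choices the defining formulas leave open, fixed here once:

* **Signed vs absolute differences.** A signed sum of first differences
  telescopes to `(X_N - X_1)/(N-1)`, which is nearly always ~0 and wastes a
  feature; the four mean-of-difference features therefore average absolute
  differences by default (`diff_absolute: true`, configurable).
* **Second-order difference** is the two-step increment `X_{n+2} - X_n`.
* **RMS of adjacent differences** divides by the number of differences
  (N-1).
* **Entropy** uses empirical frequencies of distinct integer-rounded BPM
  values, log base 2 (configurable to natural log); `0·log 0 := 0`. Bounded
  by `log2(#distinct values)`.
* **Variance of the normalized signal** is the unbiased sample variance
  (divisor N-1); every other "std" summary is the population standard
  deviation (divisor n), with singleton collections given std 0.
* **Empty run collections** (e.g. no down-runs in a monotone segment)
  produce all-zero statistics: feature vectors must stay finite and
  fixed-length, and 0 is the natural sentinel for "no such excursions".
* **Moving average** uses a hard "valid" window: a target segment shorter
  than 25 samples is an error, not a padded special case.
* **Minimum segment length** is 10 samples; below that, second-order
  differences and run statistics are meaningless.

## Mutual-information selection

Features are scored against the discrete label with the Ross (2014)
nearest-neighbor estimator (3 neighbors): scale each feature to unit
variance, add seed-controlled jitter of relative amplitude 1e-10 to break
ties among integer-valued features, take each point's distance to its 3rd
same-class neighbor, and count all points within it. Negative estimates
clamp to 0. The implementation is vectorized over samples (LOOCV re-scores
every training fold, so per-call cost matters) and is verified in the test
suite to agree exactly with scikit-learn's `mutual_info_classif` — same
scaling, same jitter stream, same formula.

Ties in the ranking are broken by canonical feature order, making selection
deterministic given scores. Features are not standardized before scoring
(the estimator is rank-based enough) and not scaled before classification
(tree models are scale-free; kNN's scale sensitivity is inherited
deliberately from the published configuration).

## Evaluation protocol

Selection happens **inside** every LOOCV fold: for held-out sample i, the
MI ranking is re-fit on the other n-1 rows before the classifier sees the
top-k columns. This is the statistically correct protocol (no test-sample
leakage through selection); `select_outside_folds: true` reproduces the
laxer variant that ranks once on the full data.

The ten evaluation runs per cell differ only in the MI estimator's jitter
seed (`rng_seed .. rng_seed+9`); classifier seeds are pinned (the random
forest carries its published seed 10; the other families' seeds are pinned
to 0, which the published settings leave open). Consequently a cell's
accuracy is a deterministic function of its seed, and run-to-run variation
reflects selection instability — the mechanism that makes mode-of-ten
reporting meaningful. The mode takes the most frequent accuracy, with ties
resolved to the smallest value; if all ten are distinct the lower median is
reported, which is always an observed value.

The three-class task keeps the tuned kNN parameters but runs the other four
families at "default configuration", as the published protocol specifies —
pinned to the defaults of the library version that protocol names
(scikit-learn 0.19.1: a 10-tree forest, 100-stage depth-3 gradient
boosting, 50-stage AdaBoost at learning rate 1.0, an unrestricted decision
tree), since the modern library has since changed some of those defaults.

`run_experiment` memoizes per-fold predictions on (family, fold,
selected-feature-set). With pinned classifier seeds a fold's prediction
depends on nothing else, so this is pure memoization; the test suite checks
the memoized path against the plain `loocv_evaluate` cell by cell.
Classifier inputs are validated finite when the feature matrix is built,
so per-fit finiteness re-checks are disabled inside the loop; likewise the
random forest's out-of-bag statistic — part of its published configuration
but never consulted for a fold model — is skipped there, which provably
leaves trees and predictions unchanged (asserted by a test).

## Synthetic sessions

No subject-level recordings of the original study are deposited, so the
generator produces sessions with the statistical structure the analysis
assumes — it is a test harness, not a cardiac model:

* subject baselines ~ Normal(72, 6) BPM;
* within a segment, heart rate follows a mean-reverting AR(1) process
  (coefficient 0.9, innovation sd 0.8 BPM), started at the stationary
  distribution and continued across the neutral/target cut for a continuous
  trace;
* the target emotion shifts the level (happy -2 BPM, sad +1 BPM by
  default — happiness lowers heart rate relative to neutral and sad states
  in the physiology literature the design draws on); sadness additionally
  scales the innovation sd by 1.5. Only sadness gets a variance effect:
  neutral-vs-happy is kept a pure mean-shift contrast so that
  normalized-mean features dominate its ranking (the structure the analysis
  expects), while happy-vs-sad deliberately is not reducible to a mean
  shift. A variance effect on happy would let per-step volatility features
  (difference std, adjacent RMS) outrank the mean family, which is exactly
  what such features are for — but it is not the study structure being
  emulated;
* values are rounded to integer BPM (producing the plateaus the flat-run
  features need) at 1 sample/s;
* neutral segments last 68–122 s and target segments 53–233 s (uniform
  integer draws over the stimulus-video duration ranges), 25 subjects x 3
  sessions by default.

Effect magnitudes are scenario parameters: the original study reports no
BPM effect sizes, so defaults were chosen as small-but-detectable values of
the cited physiological direction. What passing tests show is that the
pipeline recovers planted structure of this kind and stays at chance
without it — not that real emotions are this separable. The generator omits
motion artifacts, PPG noise, HRV beat-interval structure, and non-stationary
drifts within segments; accuracy on this synthetic family says nothing
about those failure modes.

## Problem sizes

The default study (25 subjects, 75 sessions) generates and featurizes in
well under a second. The full default grid — 4 tasks x 5 families x 6 k
values x 10 runs, with per-fold re-selection — is the expensive step
(dominated by the ~10^3 forest/boosting fits per task after memoization)
and runs in roughly a quarter of an hour on one CPU. The acceptance script
and test suite use exactly the default study conditions; the
parameter-recovery check averages 20 simulation seeds, the ranking-echo
check 10 seeds, and the zero-effect chance-band check runs the
neutral-vs-happy task (null data destabilizes selection maximally, making
it the costliest configuration per task; one pairwise task exercises every
classifier family at chance level 1/2). The acceptance script evaluates the
grid over the representative k sub-grid {20, 10, 5} — the extremes and
middle of the default selection grid — leaving the complete six-value grid
to the test suite.

## Known limitations

* LOOCV with selection inside folds is slow by construction; the memoized
  grid is the supported way to run the full comparison.
* The mode of ten near-deterministic runs can collapse to a single repeated
  value; that is faithful to the protocol, not a bug.
* kNN results depend on feature scales; no scaling is applied, matching the
  published configuration.
* Entropy rounds to integer BPM; traces at other quantizations would need a
  different binning rule.
* The generator's AR(1) assumption makes segment means estimable at
  ~0.5 BPM precision for typical durations; planted shifts below that are
  not reliably recoverable at n=25.
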