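# hrmood

Emotion recognition from nothing but wrist-wearable heart-rate traces.

Consumer bracelets and watches report integer beats-per-minute about once a
second. `hrmood` implements and evaluates a complete pipeline for deciding,
from that single channel, whether a wearer watching a stimulus was in a
neutral, happy, or sad state — the kind of lightweight affect monitoring a
commodity wearable can actually support. It is aimed at researchers in
affective computing and digital-health monitoring who need a tested,
reproducible reference implementation of the heart-rate-only approach,
together with a synthetic session generator for method development (the
original subject recordings behind this design are not publicly deposited).

## The method

Each recording session follows a **'neutral + target'** design: a neutral
video segment, then a target-emotion segment, with the emotion label
attached to the target. Resting heart rate varies far more between subjects
than emotion moves it within one, so the neutral segment's mean is used as
a per-subject baseline:

    Rate_normal(i) = Rate_original(i) − mean(Rate_neutral)

From each session, 53 features are computed — 22 from the original target
segment (first/second-difference means, range, entropy of the discrete BPM
distribution, max/min-to-length ratios, RMS of adjacent differences, and
run-duration statistics for rising / falling / plateau stretches) and 31
from the normalized signal (down-slope, up/down-amplitude, 25-sample
moving-average statistics, mean and variance, and difference-series
statistics). See `docs/FEATURES.md` for the full dictionary.

Features are ranked by mutual information with the label (nearest-neighbor
estimator, 3 neighbors) and the top k ∈ {20, 16, 12, 10, 8, 5} are fed to
five classifier families — kNN, random forest, decision tree, gradient
boosting, AdaBoost — under **leave-one-out cross-validation**, with
selection re-fit inside every fold. Accuracy is `N_correct / N_total`; each
(task, classifier, k) cell is evaluated ten times and reported as the
**mode** of the ten accuracies. Tasks are the three pairwise contrasts and
the full three-class problem.

The synthetic generator emulates the study design: 25 subjects × 3
sessions, subject baselines ~ N(72, 6) BPM, mean-reverting AR(1) dynamics
with emotion-dependent level shifts (happy −2 BPM, sad +1 BPM; sad also
noisier), integer quantization (which produces the plateaus the flat-run
features measure), and stimulus-length segments (neutral 68–122 s, target
53–233 s). `docs/methods.md` documents every modeling choice.

## Worked example

Generate a small six-subject study, extract features, and evaluate one
task with two classifiers:

```sh
hrmood simulate --out demo/data --seed 7 --subjects 6
hrmood extract --manifest demo/data/manifest.csv --out demo/features.csv
hrmood evaluate --matrix demo/features.csv --out demo/results \
    --seed 7 --tasks neutral_vs_happy --classifiers knn,gradient_boosting \
    --k-grid 5,10
```

which prints

```
wrote 18 sessions to demo/data
wrote 18 x 53 feature matrix to demo/features.csv
== neutral_vs_happy ==
k                    5       10
classifier
knn                0.75  0.7500
gradient_boosting  0.75  0.8333
best: gradient_boosting at k=10 (mode accuracy 0.8333)
```

Reading the table: each entry is the mode over ten LOOCV runs of the
fraction of held-out sessions whose emotion was predicted correctly, for
one classifier at one selection size k. This task has 12 sessions (6 per
class), so one misclassified session moves accuracy by 1/12 ≈ 0.083 and
chance level is 0.5: gradient boosting at k=10 classifies 10 of the 12
held-out sessions correctly, recovering the planted −2 BPM happy shift
well above chance even at six subjects. The full default experiment
(`hrmood all --out demo --seed 7`) runs 4 tasks × 5 classifiers × 6 k
values on a 25-subject study; expect it to take a quarter of an hour or so
on one CPU — the LOOCV-with-internal-selection protocol fits thousands of
forests and boosting ensembles.

The same pipeline is available as a library:

```python
import hrmood

sessions = hrmood.simulate_study(hrmood.SimulationConfig(seed=7))
matrix = hrmood.matrix_from_sessions(sessions)
scores = hrmood.score_mutual_information(
    matrix.restrict(("neutral", "happy")), rng_seed=7)
print(hrmood.report_top_features(hrmood.select_top_k(scores, k=5)))
```

which, at this seed, ranks the normalized-mean family on top — the
signature of a baseline-removed mean shift:

```
[('rate_data_mean', 0.344), ('25_mean_mean', 0.334), ('25_mean_median', 0.332),
 ('25_mean_max', 0.290), ('25_mean_min', 0.201)]
```
(scores are mutual-information estimates in nats, printed here to three
decimals)

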