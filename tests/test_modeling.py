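import numpy as np
import pytest
from scipy.stats import binom

from hrmood import modeling
from hrmood.errors import DegenerateFoldError, ParameterError
from hrmood.features import FEATURE_NAMES, FeatureMatrix, FeatureVector
from hrmood.io_formats import PipelineConfig
from hrmood.modeling import (
    CLASSIFIER_FAMILIES,
    TASKS,
    ClassifierSpec,
    loocv_evaluate,
    mode_of_runs,
    run_experiment,
)
from hrmood.selection import _score_array
from hrmood.modeling import _fold_rankings

CHEAP = ClassifierSpec("knn", modeling.DEFAULT_CLASSIFIER_PARAMS["knn"])


def _matrix(X, y, subjects=None):
    vectors = [
        FeatureVector(
            subject_id=subjects[i] if subjects else f"S{i}",
            emotion=label, values=row,
        )
        for i, (row, label) in enumerate(zip(X, y))
    ]
    return FeatureMatrix.from_vectors(vectors)


def _separable(n=30, seed=0, gap=10.0):
    rng = np.random.default_rng(seed)
    y = np.array(["neutral", "happy"] * (n // 2))
    X = rng.normal(size=(n, 53))
    X[:, 0] = gap * (y == "happy") + rng.normal(scale=1.0, size=n)
    return _matrix(X, y)


class TestMode:
    def test_plain_mode(self):
        assert mode_of_runs([0.8, 0.8, 0.9]) == 0.8

    def test_tie_takes_smallest(self):
        assert mode_of_runs([0.9, 0.9, 0.8, 0.8]) == 0.8

    def test_all_distinct_falls_back_to_observed_median(self):
        values = [0.1, 0.5, 0.3, 0.9, 0.7]
        assert mode_of_runs(values) == 0.5
        assert mode_of_runs(values) in values

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            mode_of_runs([])


class TestLOOCV:
    def test_separable_classes_reach_perfect_accuracy(self):
        matrix = _separable(gap=10.0)
        task = TASKS["neutral_vs_happy"]
        acc, confusion = loocv_evaluate(matrix, task, CHEAP, k=5, rng_seed=0)
        assert acc == 1.0
        assert np.trace(confusion) == 30

    def test_confusion_counts_are_consistent_with_accuracy(self):
        matrix = _separable(gap=1.0, seed=3)
        task = TASKS["neutral_vs_happy"]
        acc, confusion = loocv_evaluate(matrix, task, CHEAP, k=8, rng_seed=0)
        assert confusion.sum() == 30
        assert np.trace(confusion) == pytest.approx(acc * 30)
        assert 0.0 <= acc <= 1.0

    def test_permuted_labels_give_chance_level(self):
        # pure-noise features: LOOCV accuracy stays in the binomial 95% band
        rng = np.random.default_rng(5)
        n = 50
        y = np.array(["neutral", "happy"] * (n // 2))
        accs = []
        for seed in range(3):
            X = np.random.default_rng(seed).normal(size=(n, 53))
            acc, _ = loocv_evaluate(
                _matrix(X, y), TASKS["neutral_vs_happy"], CHEAP, k=5, rng_seed=0)
            accs.append(acc)
        lo, hi = binom.interval(0.95, n * len(accs), 0.5)
        assert lo / (n * len(accs)) <= np.mean(accs) <= hi / (n * len(accs))

    def test_deterministic_under_fixed_seed(self):
        matrix = _separable(gap=2.0, seed=7)
        task = TASKS["neutral_vs_happy"]
        a = loocv_evaluate(matrix, task, CHEAP, k=10, rng_seed=3)
        b = loocv_evaluate(matrix, task, CHEAP, k=10, rng_seed=3)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_singleton_class_rejected(self):
        rng = np.random.default_rng(0)
        y = np.array(["neutral"] * 10 + ["happy"])
        matrix = _matrix(rng.normal(size=(11, 53)), y)
        with pytest.raises(DegenerateFoldError):
            loocv_evaluate(matrix, TASKS["neutral_vs_happy"], CHEAP, k=5, rng_seed=0)

    def test_selection_for_a_fold_ignores_the_held_out_row(self):
        """No leakage: the MI ranking used for fold i cannot depend on row i."""
        matrix = _separable(gap=2.0, seed=11)
        X, y = matrix.X, matrix.y
        rankings = _fold_rankings(X, y, seed=0, outside_folds=False)
        X_corrupt = X.copy()
        X_corrupt[4] = 1e6  # wildly different held-out sample
        corrupted = _fold_rankings(X_corrupt, y, seed=0, outside_folds=False)
        assert rankings[4] == corrupted[4]

    def test_label_copy_feature_cannot_exceed_perfect(self):
        matrix = _separable(gap=10.0, seed=2)
        acc, _ = loocv_evaluate(
            matrix, TASKS["neutral_vs_happy"], CHEAP, k=1, rng_seed=0)
        assert acc <= 1.0


class TestRunExperiment:
    def _tiny_config(self, **kw):
        defaults = dict(k_grid=(5,), n_eval_runs=2, rng_seed=0)
        defaults.update(kw)
        return PipelineConfig(**defaults)

    def test_grid_shape_counts(self):
        matrix = _separable(n=24, gap=5.0)
        config = self._tiny_config(k_grid=(5, 8))
        grid = run_experiment(
            matrix, config, tasks=["neutral_vs_happy"],
            classifiers=["knn", "decision_tree"])
        assert len(grid) == 1 * 2 * 2
        for cell in grid:
            assert cell.error is None
            assert len(cell.run_accuracies) == 2

    def test_memoized_grid_equals_direct_loocv(self):
        """The memoized experiment path reproduces loocv_evaluate exactly."""
        matrix = _separable(n=26, gap=1.5, seed=9)
        config = self._tiny_config()
        grid = run_experiment(
            matrix, config, tasks=["neutral_vs_happy"],
            classifiers=["knn", "decision_tree"])
        task = TASKS["neutral_vs_happy"]
        for cell in grid:
            spec = modeling.default_spec(cell.classifier, task)
            for run, acc in enumerate(cell.run_accuracies):
                direct, _ = loocv_evaluate(
                    matrix, task, spec, k=cell.k, rng_seed=config.rng_seed + run)
                assert acc == direct

    def test_deterministic_classifiers_give_identical_runs(self):
        # with pinned classifier seeds and a stable ranking, all runs agree
        matrix = _separable(n=24, gap=20.0, seed=4)
        grid = run_experiment(
            matrix, self._tiny_config(n_eval_runs=4),
            tasks=["neutral_vs_happy"], classifiers=["knn", "decision_tree"])
        for cell in grid:
            assert len(set(cell.run_accuracies)) == 1
            assert cell.mode_accuracy == cell.run_accuracies[0]

    def test_mode_belongs_to_run_accuracies(self):
        matrix = _separable(n=26, gap=1.0, seed=6)
        grid = run_experiment(
            matrix, self._tiny_config(n_eval_runs=3),
            tasks=["neutral_vs_happy"], classifiers=["knn"])
        for cell in grid:
            assert cell.mode_accuracy in cell.run_accuracies

    def test_missing_class_recorded_as_error_marker(self):
        matrix = _separable(n=20, gap=1.0)  # no 'sad' rows at all
        grid = run_experiment(
            matrix, self._tiny_config(), tasks=["happy_vs_sad"],
            classifiers=["knn"])
        assert all(cell.error is not None for cell in grid)

    def test_summary_reports_best_cell(self):
        matrix = _separable(n=24, gap=8.0)
        grid = run_experiment(
            matrix, self._tiny_config(), tasks=["neutral_vs_happy"],
            classifiers=["knn"])
        text = modeling.summarize_results(grid)
        assert "neutral_vs_happy" in text
        assert "best:" in text

    def test_empty_grid_summary_does_not_crash(self):
        assert modeling.summarize_results([]) == "no results\n"

    def test_forest_predictions_independent_of_oob_scoring(self):
        """Skipping the (unused) OOB statistic inside the LOOCV loop cannot
        change predictions: the bootstrap draws precede OOB scoring."""
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(3)
        X = rng.normal(size=(49, 12))
        y = np.array(["neutral", "happy"] * 25)[:49]
        Xt = rng.normal(size=(30, 12))
        preds = [
            RandomForestClassifier(
                n_estimators=90, oob_score=oob, random_state=10
            ).fit(X, y).predict(Xt)
            for oob in (True, False)
        ]
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_table_defaults_match_published_settings(self):
        knn = modeling.DEFAULT_CLASSIFIER_PARAMS["knn"]
        assert knn == {
            "n_neighbors": 6, "weights": "distance", "p": 1,
            "leaf_size": 2, "algorithm": "ball_tree",
        }
        rf = modeling.DEFAULT_CLASSIFIER_PARAMS["random_forest"]
        assert rf["n_estimators"] == 90 and rf["oob_score"] is True
        assert rf["random_state"] == 10
        gb = modeling.DEFAULT_CLASSIFIER_PARAMS["gradient_boosting"]
        assert (gb["n_estimators"], gb["max_depth"], gb["learning_rate"],
                gb["min_samples_split"], gb["subsample"]) == (120, 10, 0.01, 4, 0.5)
        ada = modeling.DEFAULT_CLASSIFIER_PARAMS["adaboost"]
        assert (ada["n_estimators"], ada["learning_rate"]) == (6, 0.1)
        assert set(CLASSIFIER_FAMILIES) == {
            "knn", "random_forest", "decision_tree", "gradient_boosting",
            "adaboost",
        }
        # the three-class task keeps tuned kNN but protocol-era defaults
        # elsewhere (10-tree forest, 100x depth-3 boosting, 50-stage ada)
        three = modeling.THREE_CLASS_CLASSIFIER_PARAMS
        assert three["knn"] == knn
        assert three["random_forest"]["n_estimators"] == 10
        assert three["gradient_boosting"]["n_estimators"] == 100
        assert three["adaboost"]["n_estimators"] == 50
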