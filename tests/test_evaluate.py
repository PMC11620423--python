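"""One-vs-rest metrics and the repeated stratified CV harness."""

import numpy as np
import pytest

from ramanglu import (
    CvConfig,
    ModelSpec,
    build_classifier,
    evaluate_repeated_cv,
    grid_search,
    ovr_metrics,
)
from ramanglu.errors import (
    DegenerateClassWarning,
    InvalidGrid,
    StratificationError,
)


def _separable(n_per_class=10, n_classes=2, gap=50.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate(
        [
            gap * c + rng.normal(0, 0.5, size=(n_per_class, 4))
            for c in range(n_classes)
        ]
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    return X, y


class TestOvrMetrics:
    def test_perfect_predictions(self):
        y = [1, 2, 3, 1, 2, 3]
        scores = np.eye(3)[np.array(y) - 1]
        m = ovr_metrics(y, y, class_scores=scores)
        assert m["accuracy"] == 1.0
        assert m["ovr_accuracy"] == 1.0
        assert m["specificity"] == 1.0
        assert m["sensitivity"] == 1.0
        assert m["auc"] == 1.0

    def test_two_class_hand_example(self):
        # class-1 OvR table: TP=3, FN=1, FP=1, TN=3
        true = [1, 1, 1, 1, 2, 2, 2, 2]
        pred = [1, 1, 2, 1, 2, 2, 1, 2]
        m = ovr_metrics(true, pred)
        c1 = m["per_class"][1]
        assert (c1["TP"], c1["FN"], c1["FP"], c1["TN"]) == (3, 1, 1, 3)
        assert c1["sensitivity"] == 0.75
        assert c1["specificity"] == 0.75
        assert c1["accuracy"] == 0.75
        assert m["sensitivity"] == 0.75
        assert m["specificity"] == 0.75
        assert m["ovr_accuracy"] == 0.75
        assert m["accuracy"] == 0.75

    def test_thirty_sample_hand_example(self):
        # 3 classes x 10; class 1 fully correct, class 2 sends 4 to class
        # 3, class 3 sends 2 to class 1. Tables computed by hand:
        # c1: TP=10 FN=0 FP=2 TN=18; c2: TP=6 FN=4 FP=0 TN=20;
        # c3: TP=8 FN=2 FP=4 TN=16.
        true = [1] * 10 + [2] * 10 + [3] * 10
        pred = [1] * 10 + [2] * 6 + [3] * 4 + [3] * 8 + [1] * 2
        m = ovr_metrics(true, pred)
        assert m["per_class"][1]["sensitivity"] == 1.0
        assert m["per_class"][2]["sensitivity"] == 0.6
        assert m["per_class"][3]["specificity"] == 0.8
        assert m["accuracy"] == 24 / 30
        assert m["sensitivity"] == pytest.approx((1.0 + 0.6 + 0.8) / 3)
        assert m["specificity"] == pytest.approx(
            (18 / 20 + 20 / 20 + 16 / 20) / 3
        )
        assert m["ovr_accuracy"] == pytest.approx(
            (28 / 30 + 26 / 30 + 24 / 30) / 3
        )

    def test_all_wrong_predictions(self):
        true = [1, 1, 2, 2]
        pred = [2, 2, 1, 1]
        m = ovr_metrics(true, pred)
        assert m["accuracy"] == 0.0
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 0.0

    def test_degenerate_class_excluded_with_warning(self):
        with pytest.warns(DegenerateClassWarning):
            m = ovr_metrics([1, 1, 2], [1, 3, 2], classes=[1, 2, 3])
        assert np.isnan(m["per_class"][3]["sensitivity"])
        # macro averages computed over classes 1 and 2 only
        assert m["sensitivity"] == pytest.approx((0.5 + 1.0) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ovr_metrics([1, 2], [1])

    def test_micro_consistency_tp_sum_equals_correct_count(self, rng):
        true = rng.integers(1, 6, size=100)
        pred = rng.integers(1, 6, size=100)
        m = ovr_metrics(true, pred)
        tp_sum = sum(c["TP"] for c in m["per_class"].values())
        assert tp_sum == int(np.sum(true == pred))

    def test_se_sp_invariant_to_negative_relabeling(self, rng):
        true = rng.integers(1, 5, size=60)
        pred = rng.integers(1, 5, size=60)
        m1 = ovr_metrics(true, pred)
        # swap labels 3 and 4 everywhere: class 1's OvR table unchanged
        swap = {1: 1, 2: 2, 3: 4, 4: 3}
        m2 = ovr_metrics(
            [swap[v] for v in true], [swap[v] for v in pred]
        )
        assert m1["per_class"][1] == m2["per_class"][1]

    def test_auc_from_scores_is_rank_based(self):
        true = [1, 1, 2, 2]
        scores = np.array(
            [[0.9, 0.1], [0.6, 0.4], [0.4, 0.6], [0.2, 0.8]]
        )
        m = ovr_metrics(true, [1, 1, 2, 2], class_scores=scores, classes=[1, 2])
        assert m["auc"] == 1.0


class TestRepeatedCv:
    def test_reproducibility(self):
        X, y = _separable(n_per_class=10, n_classes=3, gap=2.0)
        cv = CvConfig(k=5, n_repeats=3, seed=42)
        spec = ModelSpec("extra_trees", {"n_estimators": 10}, seed=1)
        a = evaluate_repeated_cv(X, y, spec, cv)
        b = evaluate_repeated_cv(X, y, spec, cv)
        assert a.means == b.means
        assert a.iteration_metrics == b.iteration_metrics

    def test_iteration_count(self):
        X, y = _separable(n_per_class=5, n_classes=4)
        rep = evaluate_repeated_cv(
            X,
            y,
            ModelSpec("extra_trees", {"n_estimators": 5}),
            CvConfig(k=5, n_repeats=4, seed=0),
        )
        assert rep.n_iterations == 20

    def test_separable_data_perfect_accuracy(self):
        X, y = _separable(n_per_class=10, n_classes=2, gap=100.0)
        for name in ("extra_trees", "random_forest", "svm"):
            hp = {"n_estimators": 20} if name != "svm" else {}
            rep = evaluate_repeated_cv(
                X, y, ModelSpec(name, hp), CvConfig(k=5, n_repeats=2, seed=3)
            )
            assert rep.means["accuracy"] == 1.0

    def test_fold_bookkeeping_each_sample_tested_once_per_repeat(self):
        from sklearn.model_selection import RepeatedStratifiedKFold

        y = np.repeat(np.arange(10), 5)
        splitter = RepeatedStratifiedKFold(
            n_splits=5, n_repeats=3, random_state=0
        )
        splits = list(splitter.split(np.zeros((50, 1)), y))
        for r in range(3):
            seen = np.concatenate(
                [test for _, test in splits[r * 5 : (r + 1) * 5]]
            )
            assert sorted(seen) == list(range(50))
        for train, test in splits:
            assert set(train).isdisjoint(test)

    def test_stratification_error_when_class_too_small(self):
        X = np.zeros((7, 2))
        y = np.array([1, 1, 1, 1, 1, 2, 2])
        with pytest.raises(StratificationError):
            evaluate_repeated_cv(
                X, y, ModelSpec("extra_trees"), CvConfig(k=5, n_repeats=1)
            )

    def test_one_sample_per_class_in_each_test_fold(self, small_dataset):
        # balanced 10x3 design, k=3: every test fold holds one of each class
        from sklearn.model_selection import RepeatedStratifiedKFold

        y = small_dataset.labels()
        splitter = RepeatedStratifiedKFold(
            n_splits=3, n_repeats=2, random_state=1
        )
        for _, test in splitter.split(np.zeros((len(y), 1)), y):
            _, counts = np.unique(y[test], return_counts=True)
            assert counts.tolist() == [1] * 10


class TestModelSpec:
    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidGrid):
            ModelSpec("gradient_boosting")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(InvalidGrid):
            ModelSpec("svm", {"n_estimators": 10})
        with pytest.raises(InvalidGrid):
            ModelSpec("extra_trees", {"C": 1.0})

    def test_valid_hyperparameters_accepted(self):
        ModelSpec(
            "random_forest",
            {
                "n_estimators": 10,
                "max_features": "sqrt",
                "max_depth": 3,
                "max_leaf_nodes": 8,
                "min_samples_split": 2,
                "min_samples_leaf": 1,
            },
        )
        ModelSpec("svm", {"C": 1.0, "kernel": "rbf", "gamma": "scale", "degree": 3})

    def test_build_classifier_types(self):
        from sklearn.ensemble import ExtraTreesClassifier
        from sklearn.svm import SVC

        assert isinstance(
            build_classifier(ModelSpec("extra_trees")), ExtraTreesClassifier
        )
        assert isinstance(build_classifier(ModelSpec("svm")), SVC)


class TestGridSearch:
    def test_single_combination_returned_as_is(self):
        X, y = _separable(n_per_class=6, n_classes=2, gap=10.0)
        best, rep = grid_search(
            X,
            y,
            "extra_trees",
            {"n_estimators": [7]},
            CvConfig(k=3, n_repeats=1, seed=0),
        )
        assert best == {"n_estimators": 7}
        assert rep.n_iterations == 3

    def test_two_arm_selection_matches_direct_evaluation(self, rng):
        # noisy separable set where a bigger ensemble is measurably better
        X = np.concatenate(
            [
                c * 1.0 + rng.normal(0, 1.2, size=(10, 6))
                for c in range(2)
            ]
        )
        y = np.repeat([0, 1], 10)
        cv = CvConfig(k=5, n_repeats=4, seed=2)
        best, rep = grid_search(
            X, y, "extra_trees", {"n_estimators": [1, 200]}, cv
        )
        arms = {
            n: evaluate_repeated_cv(
                X, y, ModelSpec("extra_trees", {"n_estimators": n}), cv
            ).means["accuracy"]
            for n in (1, 200)
        }
        assert best["n_estimators"] == max(arms, key=arms.get)
        assert rep.means["accuracy"] == arms[best["n_estimators"]]

    def test_invalid_grid_key_rejected(self):
        X, y = _separable(n_per_class=4)
        with pytest.raises(InvalidGrid):
            grid_search(X, y, "svm", {"n_estimators": [1]})

    def test_parallel_matches_serial(self):
        X, y = _separable(n_per_class=6, n_classes=2, gap=3.0, seed=5)
        cv = CvConfig(k=3, n_repeats=2, seed=0)
        grid = {"n_estimators": [5, 20], "min_samples_split": [2, 4]}
        serial = grid_search(X, y, "extra_trees", grid, cv, n_jobs=1)
        parallel = grid_search(X, y, "extra_trees", grid, cv, n_jobs=2)
        assert serial[0] == parallel[0]
        assert serial[1].means == parallel[1].means
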