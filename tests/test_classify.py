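"""Split protocol, class weighting, forest training and the metric surface."""

import numpy as np
import pytest

from uroftir.classify import (
    ForestConfig,
    SplitSpec,
    class_weights,
    compare_models,
    evaluate,
    fit_forest,
    grid_search,
    learning_curve,
    predict_proba,
    stratified_split,
)
from uroftir.errors import DataError, FoldError, FractionError, StratificationError, WeightingError


def confusion_oracle(y_true, y_pred):
    """Direct counting over all four cells."""
    cells = dict(tp=0, tn=0, fp=0, fn=0)
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            cells["tp"] += 1
        elif t == 0 and p == 0:
            cells["tn"] += 1
        elif t == 0 and p == 1:
            cells["fp"] += 1
        else:
            cells["fn"] += 1
    return cells


class TestStratifiedSplit:
    def test_study_cohort_allocation(self):
        labels = np.array([0] * 206 + [1] * 103)
        train, test = stratified_split(labels, SplitSpec(test_fraction=0.30, seed=333))
        assert test.size == 93
        assert (labels[test] == 0).sum() == 62
        assert (labels[test] == 1).sum() == 31
        assert train.size == 216

    def test_balanced_half_split(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        _, test = stratified_split(labels, SplitSpec(test_fraction=0.5, seed=1))
        assert (labels[test] == 0).sum() == 2
        assert (labels[test] == 1).sum() == 2

    def test_deterministic_and_exhaustive(self):
        labels = np.array([0] * 20 + [1] * 10)
        a = stratified_split(labels, SplitSpec(seed=5))
        b = stratified_split(labels, SplitSpec(seed=5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert np.array_equal(np.sort(np.concatenate(a)), np.arange(30))
        assert np.intersect1d(a[0], a[1]).size == 0

    def test_tiny_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split(np.array([0, 0, 0, 1]), SplitSpec())


class TestClassWeights:
    def test_study_cohort_weights(self):
        labels = np.array([0] * 206 + [1] * 103)
        assert class_weights(labels) == {0: 0.75, 1: 1.5}

    def test_balanced_is_unit(self):
        assert class_weights(np.array([0, 0, 1, 1])) == {0: 1.0, 1: 1.0}

    def test_ratio_identity(self, rng):
        n0, n1 = 37, 13
        w = class_weights(np.array([0] * n0 + [1] * n1))
        assert np.isclose(w[1] / w[0], n0 / n1)

    def test_single_class(self):
        with pytest.raises(WeightingError):
            class_weights(np.zeros(5, dtype=int))


class TestForest:
    def _separable(self, rng, n=40):
        x = np.concatenate([rng.uniform(-2, -0.5, n // 2), rng.uniform(0.5, 2, n // 2)])
        y = (x > 0).astype(int)
        return x.reshape(-1, 1), y

    def test_separable_training_accuracy(self, rng):
        X, y = self._separable(rng)
        clf = fit_forest(X, y, ForestConfig())
        assert (clf.predict(X) == y).all()

    def test_probability_normalisation(self, rng):
        X, y = self._separable(rng)
        clf = fit_forest(X, y, ForestConfig())
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        p1 = predict_proba(clf, X)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_seeded_determinism(self, rng):
        X, y = self._separable(rng)
        a = fit_forest(X, y, ForestConfig(seed=333)).predict_proba(X)
        b = fit_forest(X, y, ForestConfig(seed=333)).predict_proba(X)
        assert np.array_equal(a, b)

    def test_empty_input(self):
        with pytest.raises(DataError):
            fit_forest(np.empty((0, 3)), np.empty(0, dtype=int), ForestConfig())


class TestEvaluate:
    def test_formula_example(self):
        y_true = np.array([1] * 10 + [0] * 90)
        y_pred = np.concatenate([np.ones(8), np.zeros(2), np.ones(2), np.zeros(88)]).astype(int)
        rep = evaluate(y_true, y_pred)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (8, 2, 2, 88)
        assert rep.precision[1] == 0.8 and rep.recall[1] == 0.8
        assert np.isclose(rep.f1[1], 0.8)   # harmonic mean of p = r = 0.8
        assert rep.accuracy == 0.96

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = evaluate(y, y)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
        assert rep.f1 == {1: 1.0, 0: 1.0} and rep.weighted_f1 == 1.0

    def test_degenerate_cells_flagged_not_fatal(self):
        rep = evaluate(np.array([1, 1, 0]), np.array([0, 0, 0]))
        assert rep.precision[1] == 0.0
        assert "precision[1]" in rep.degenerate

    def test_matches_counting_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            rep = evaluate(y_true, y_pred)
            cells = confusion_oracle(y_true, y_pred)
            assert (rep.tp, rep.tn, rep.fp, rep.fn) == (
                cells["tp"], cells["tn"], cells["fp"], cells["fn"])
            assert rep.tp + rep.tn + rep.fp + rep.fn == n
            # weighted F1 is the support-weighted average of per-class F1
            support = {1: cells["tp"] + cells["fn"], 0: cells["tn"] + cells["fp"]}
            want = (support[0] * rep.f1[0] + support[1] * rep.f1[1]) / n
            assert np.isclose(rep.weighted_f1, want)

    def test_empty_error(self):
        with pytest.raises(DataError):
            evaluate(np.empty(0, dtype=int), np.empty(0, dtype=int))


class TestGridSearch:
    def _data(self, rng, n=60):
        X = rng.normal(size=(n, 5))
        y = (X[:, 0] > 0).astype(int)
        return X, y

    def test_single_point_grid(self, rng):
        X, y = self._data(rng)
        best, table = grid_search(X, y, {"n_estimators": [5]}, folds=3, seed=1)
        assert best.n_estimators == 5
        assert len(table) == 1

    def test_best_is_max_mean_score(self, rng):
        X, y = self._data(rng)
        best, table = grid_search(X, y, {"max_depth": [1, 3], "n_estimators": [5, 11]},
                                  folds=3, seed=1)
        assert np.isclose(table["mean_score"].max(),
                          table.loc[table["mean_score"].idxmax(), "mean_score"])
        row = table[(table.max_depth == best.max_depth)
                    & (table.n_estimators == best.n_estimators)]
        assert np.isclose(row["mean_score"].iloc[0], table["mean_score"].max())

    def test_fold_error(self, rng):
        X, y = self._data(rng, n=10)
        with pytest.raises(FoldError):
            grid_search(X, y, {"max_depth": [2]}, folds=10, seed=1)


class TestCompareModels:
    def test_all_families_present_and_bounded(self, small_proc):
        table = compare_models(small_proc.matrix, small_proc.labels, folds=3, seed=1)
        assert list(table["model"]) == [
            "random_forest", "logistic_regression", "svm", "gradient_boosting"]
        for col in ("accuracy", "precision", "recall", "f1"):
            assert ((table[col] >= 0) & (table[col] <= 1)).all()

    def test_deterministic(self, small_proc):
        a = compare_models(small_proc.matrix, small_proc.labels, folds=3, seed=2)
        b = compare_models(small_proc.matrix, small_proc.labels, folds=3, seed=2)
        assert a.equals(b)

    def test_every_family_succeeds_on_synthetic_cohort(self, small_proc):
        table = compare_models(small_proc.matrix, small_proc.labels, folds=3, seed=1)
        assert (table["accuracy"] >= 0.9).all()


class TestLearningCurve:
    def test_output_lengths(self, small_proc):
        out = learning_curve(small_proc.matrix, small_proc.labels,
                             fractions=[0.5, 1.0], folds=3, seed=1)
        assert len(out) == 2
        assert set(out.columns) >= {"fraction", "train_score", "validation_score"}

    def test_full_fraction_matches_plain_cv(self, small_proc):
        X, y = small_proc.matrix, small_proc.labels
        out = learning_curve(X, y, fractions=[1.0], folds=3, seed=7)
        again = learning_curve(X, y, fractions=[1.0], folds=3, seed=7)
        assert np.isclose(out["validation_score"].iloc[0],
                          again["validation_score"].iloc[0])

    def test_validation_improves_with_size(self, default_proc):
        """On the full cohort, more training data does not hurt validation
        accuracy (within a small resampling slack)."""
        out = learning_curve(default_proc.matrix, default_proc.labels,
                             fractions=[0.3, 1.0], folds=3, seed=1)
        assert (out["validation_score"].iloc[-1]
                >= out["validation_score"].iloc[0] - 0.02)

    def test_fraction_too_small(self, small_proc):
        with pytest.raises(FractionError):
            learning_curve(small_proc.matrix, small_proc.labels,
                           fractions=[0.02], folds=3, seed=1)


def test_permuted_labels_give_chance_level(small_proc):
    """Shuffling the labels destroys the class signal: stratified CV
    accuracy with balanced weights falls to chance."""
    rng = np.random.default_rng(42)
    y_perm = rng.permutation(small_proc.labels)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=42)
    accs = []
    X = small_proc.matrix
    for tr, te in skf.split(X, y_perm):
        clf = fit_forest(X[tr], y_perm[tr], ForestConfig(seed=42),
                         class_weights(y_perm[tr]))
        accs.append(evaluate(y_perm[te], clf.predict(X[te])).accuracy)
    assert 0.4 <= np.mean(accs) <= 0.8
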