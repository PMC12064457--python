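"""Random-forest classification with the study's split/weighting protocol.

The protocol: stratified 70/30 train/test split with a fixed seed (333),
class weights inversely proportional to class frequencies, and a random
forest with the tuned configuration (21 trees, maximum depth 4, minimum
split 8, minimum leaf 2, Gini impurity).  Evaluation reports the complete
confusion-derived metric surface per class plus weighted F1, accuracy,
sensitivity, specificity and AUC.

Model fitting is delegated to scikit-learn; the split, the class-weight
convention and the metric formulas are implemented here so they follow the
study's definitions exactly (largest-remainder stratified allocation,
w_c = N / (2 n_c), per-class precision/recall/F1 with either class as the
positive label).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.svm import SVC

from .errors import (
    DataError,
    FoldError,
    FractionError,
    StratificationError,
    WeightingError,
)
from .latent import roc_auc

__all__ = [
    "ForestConfig",
    "SplitSpec",
    "MetricsReport",
    "stratified_split",
    "class_weights",
    "fit_forest",
    "predict_proba",
    "grid_search",
    "evaluate",
    "compare_models",
    "learning_curve",
]

#: the study's fixed seed for all random operations
DEFAULT_SEED = 333


@dataclass(frozen=True)
class ForestConfig:
    """Tuned random-forest hyperparameters from the study's grid search."""

    criterion: str = "gini"
    n_estimators: int = 21
    max_depth: int = 4
    min_samples_split: int = 8
    min_samples_leaf: int = 2
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.criterion not in ("gini", "entropy"):
            raise ValueError("criterion must be 'gini' or 'entropy'")
        for name in ("n_estimators", "max_depth", "min_samples_split", "min_samples_leaf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split specification (70/30 by default)."""

    test_fraction: float = 0.30
    stratified: bool = True
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class MetricsReport:
    """Confusion counts and the derived per-class / aggregate metrics.

    Per-class metrics treat that class as the positive label; sensitivity
    and specificity follow the clinical convention (class 1 = disease).
    ``degenerate`` lists metrics that hit a 0/0 ratio and were set to 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    weighted_f1: float
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["precision"] = {str(k): v for k, v in self.precision.items()}
        d["recall"] = {str(k): v for k, v in self.recall.items()}
        d["f1"] = {str(k): v for k, v in self.f1.items()}
        return d


def stratified_split(labels: Sequence[int], spec: SplitSpec = SplitSpec()
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified split with largest-remainder allocation.

    The total test size is ``round(test_fraction * N)``; per-class test
    counts start at the floor of ``test_fraction * n_c`` and the remaining
    slots go to the classes with the largest fractional remainders.
    Returns (train_indices, test_indices), each sorted.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(spec.seed)
    classes, counts = np.unique(labels, return_counts=True)
    if spec.stratified and np.any(counts < 2):
        raise StratificationError("every class needs >= 2 members to stratify")

    n_total = labels.size
    n_test_total = int(round(spec.test_fraction * n_total))
    quotas = spec.test_fraction * counts
    base = np.floor(quotas).astype(int)
    remainders = quotas - base
    short = n_test_total - int(base.sum())
    # hand leftover slots to the largest remainders; ties broken by class order
    order = np.argsort(-remainders, kind="stable")
    take = base.copy()
    for i in range(short):
        take[order[i % len(classes)]] += 1

    test_idx: list[int] = []
    for cls, n_test_c in zip(classes, take):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members.size)
        test_idx.extend(members[perm[:n_test_c]])
    test = np.sort(np.asarray(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(n_total), test)
    return train, test


def class_weights(labels: Sequence[int]) -> dict[int, float]:
    """Balanced weights w_c = N / (K * n_c), inverse to class frequency."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise WeightingError("class weights undefined for a single class")
    n = labels.size
    return {int(c): n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def fit_forest(X: np.ndarray, y: Sequence[int],
               config: ForestConfig = ForestConfig(),
               weights: dict[int, float] | None = None) -> RandomForestClassifier:
    """Train the constrained random forest (seeded, hence bit-reproducible)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.size == 0 or X.shape[0] != y.size:
        raise DataError("empty X or mismatched y")
    clf = RandomForestClassifier(
        criterion=config.criterion,
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        min_samples_leaf=config.min_samples_leaf,
        class_weight=weights,
        random_state=config.seed,
    )
    clf.fit(X, y)
    return clf


def predict_proba(clf: RandomForestClassifier, X_new: np.ndarray) -> np.ndarray:
    """Class-1 probability per row."""
    proba = clf.predict_proba(np.atleast_2d(np.asarray(X_new, dtype=float)))
    return proba[:, list(clf.classes_).index(1)]


def _safe_ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def evaluate(y_true: Sequence[int], y_pred: Sequence[int],
             scores: Sequence[float] | None = None) -> MetricsReport:
    """Full metric surface from the confusion matrix (class 1 positive).

    Per-class precision/recall/F1 are computed twice, once with each class
    as the positive label; 0/0 ratios become 0 and are flagged in
    ``degenerate`` so cross-validation never aborts.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise DataError("empty or mismatched inputs")

    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    degenerate: list[str] = []
    precision, recall, f1 = {}, {}, {}
    for cls, (tp_c, fp_c, fn_c) in {1: (tp, fp, fn), 0: (tn, fn, fp)}.items():
        p = _safe_ratio(tp_c, tp_c + fp_c, f"precision[{cls}]", degenerate)
        r = _safe_ratio(tp_c, tp_c + fn_c, f"recall[{cls}]", degenerate)
        precision[cls] = p
        recall[cls] = r
        f1[cls] = _safe_ratio(2 * p * r, p + r, f"f1[{cls}]", degenerate)

    support = {1: tp + fn, 0: tn + fp}
    total = y_true.size
    weighted_f1 = (support[0] * f1[0] + support[1] * f1[1]) / total
    accuracy = (tp + tn) / total
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity", degenerate)
    specificity = _safe_ratio(tn, tn + fp, "specificity", degenerate)
    auc = None
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = roc_auc(y_true, np.asarray(scores, dtype=float))["auc"]
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, precision=precision,
                         recall=recall, f1=f1, weighted_f1=weighted_f1,
                         accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, auc=auc,
                         degenerate=sorted(set(degenerate)))


def _cv_folds(y: np.ndarray, folds: int, seed: int) -> StratifiedKFold:
    counts = np.bincount(y)
    if folds < 2 or folds > counts[counts > 0].min():
        raise FoldError(f"fold count {folds} exceeds the minority-class size")
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def grid_search(X: np.ndarray, y: Sequence[int], grid: dict[str, list],
                folds: int = 10, seed: int = DEFAULT_SEED,
                scorer: str = "weighted_f1") -> tuple[ForestConfig, pd.DataFrame]:
    """Exhaustive stratified k-fold search over forest hyperparameters.

    Scored by support-weighted F1 by default (``scorer='accuracy'`` for the
    alternative); ties broken by declared grid order.  Returns the winning
    configuration and the per-candidate score table for audit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if any(len(v) == 0 for v in grid.values()):
        raise ValueError("every grid axis must be non-empty")
    skf = _cv_folds(y, folds, seed)
    splits = list(skf.split(X, y))
    weights = class_weights(y)

    records = []
    for params in ParameterGrid(grid):
        config = ForestConfig(**{**{"seed": seed}, **params})
        fold_scores = []
        for tr, te in splits:
            clf = fit_forest(X[tr], y[tr], config, weights)
            rep = evaluate(y[te], clf.predict(X[te]))
            fold_scores.append(getattr(rep, scorer) if scorer == "accuracy"
                               else rep.weighted_f1)
        records.append({**params, "mean_score": float(np.mean(fold_scores))})
    table = pd.DataFrame.from_records(records)
    best_row = int(table["mean_score"].values.argmax())  # first max = grid order
    best_params = {k: records[best_row][k] for k in records[best_row] if k != "mean_score"}
    return ForestConfig(**{**{"seed": seed}, **best_params}), table


_COMPARED_MODELS = ("random_forest", "logistic_regression", "svm", "gradient_boosting")


def _make_model(name: str, config: ForestConfig, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(
            criterion=config.criterion, n_estimators=config.n_estimators,
            max_depth=config.max_depth, min_samples_split=config.min_samples_split,
            min_samples_leaf=config.min_samples_leaf, class_weight="balanced",
            random_state=seed)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=5000, class_weight="balanced")
    if name == "svm":
        return SVC(class_weight="balanced", random_state=seed)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(name)


def compare_models(X: np.ndarray, y: Sequence[int], folds: int = 5,
                   seed: int = DEFAULT_SEED,
                   forest_config: ForestConfig = ForestConfig()) -> pd.DataFrame:
    """Mean CV accuracy/precision/recall/F1 for the four model families.

    All families share the same stratified folds and seed, so differences
    reflect the models, not the resampling.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = _cv_folds(y, folds, seed)
    splits = list(skf.split(X, y))

    rows = []
    for name in _COMPARED_MODELS:
        accs, precs, recs, f1s = [], [], [], []
        for tr, te in splits:
            model = _make_model(name, forest_config, seed)
            model.fit(X[tr], y[tr])
            rep = evaluate(y[te], model.predict(X[te]))
            accs.append(rep.accuracy)
            support = {c: int(np.sum(y[te] == c)) for c in (0, 1)}
            total = sum(support.values())
            precs.append(sum(rep.precision[c] * support[c] for c in (0, 1)) / total)
            recs.append(sum(rep.recall[c] * support[c] for c in (0, 1)) / total)
            f1s.append(rep.weighted_f1)
        rows.append({"model": name, "accuracy": np.mean(accs),
                     "precision": np.mean(precs), "recall": np.mean(recs),
                     "f1": np.mean(f1s)})
    return pd.DataFrame(rows)


def learning_curve(X: np.ndarray, y: Sequence[int], fractions: Sequence[float],
                   folds: int = 5, seed: int = DEFAULT_SEED,
                   config: ForestConfig = ForestConfig()) -> pd.DataFrame:
    """Train/validation accuracy as a function of training-set size.

    For each fraction a stratified subsample is drawn (largest-remainder
    allocation, seeded) and scored by stratified k-fold CV; fraction 1.0
    reproduces the plain CV score at the same seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rows = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise FractionError(f"fraction {frac} outside (0, 1]")
        if frac < 1.0:
            # reuse the stratified splitter: "test" side = the subsample
            try:
                _, sub = stratified_split(y, SplitSpec(test_fraction=frac, seed=seed))
            except StratificationError as exc:
                raise FractionError(str(exc)) from exc
            if np.bincount(y[sub], minlength=2).min() < folds:
                raise FractionError(f"fraction {frac} too small for {folds} folds")
        else:
            sub = np.arange(y.size)
        Xs, ys = X[sub], y[sub]
        skf = _cv_folds(ys, folds, seed)
        tr_scores, va_scores = [], []
        weights = class_weights(ys)
        for tr, te in skf.split(Xs, ys):
            clf = fit_forest(Xs[tr], ys[tr], config, weights)
            tr_scores.append(evaluate(ys[tr], clf.predict(Xs[tr])).accuracy)
            va_scores.append(evaluate(ys[te], clf.predict(Xs[te])).accuracy)
        rows.append({"fraction": frac, "n_samples": int(sub.size),
                     "train_score": float(np.mean(tr_scores)),
                     "validation_score": float(np.mean(va_scores))})
    return pd.DataFrame(rows)
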