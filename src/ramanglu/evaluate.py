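"""Classifier training and evaluation under repeated stratified k-fold CV.

Three classifier families are compared — Extra Trees, Random Forest and a
support-vector machine — each scored with one-vs-rest (OvR) metrics. For
each class c the OvR confusion table (positive = c, negative = everything
else) gives

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Sp  = TN / (TN + FP)
    Se  = TP / (TP + FN)

macro-averaged over classes, plus a rank-based OvR ROC-AUC and the plain
multiclass fraction-correct. Evaluation repeats a stratified k-fold split
many times with fresh shuffles (the default 5 folds x 90 repeats = 450
train/test iterations) and averages the per-iteration metrics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .errors import DegenerateClassWarning, InvalidGrid, StratificationError

MODEL_NAMES = ("extra_trees", "random_forest", "svm")

#: Hyperparameters each model accepts for tuning.
VALID_HYPERPARAMS: dict[str, frozenset[str]] = {
    "extra_trees": frozenset(
        {
            "n_estimators",
            "max_features",
            "max_depth",
            "max_leaf_nodes",
            "min_samples_split",
            "min_samples_leaf",
        }
    ),
    "random_forest": frozenset(
        {
            "n_estimators",
            "max_features",
            "max_depth",
            "max_leaf_nodes",
            "min_samples_split",
            "min_samples_leaf",
        }
    ),
    "svm": frozenset({"C", "kernel", "gamma", "degree"}),
}

#: Modest default search grids over the tunable hyperparameter names.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "extra_trees": {
        "n_estimators": [100, 300],
        "max_features": ["sqrt", 0.2],
        "min_samples_split": [2, 4],
    },
    "random_forest": {
        "n_estimators": [100, 300],
        "max_features": ["sqrt", 0.2],
        "min_samples_split": [2, 4],
    },
    "svm": {
        "C": [0.1, 1.0, 10.0],
        "kernel": ["rbf", "linear"],
        "gamma": ["scale"],
    },
}


@dataclass
class ModelSpec:
    """A named classifier plus its hyperparameters and seed."""

    name: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in VALID_HYPERPARAMS:
            raise InvalidGrid(
                f"unknown model {self.name!r}; expected one of {MODEL_NAMES}"
            )
        unknown = set(self.hyperparams) - VALID_HYPERPARAMS[self.name]
        if unknown:
            raise InvalidGrid(
                f"{self.name} does not accept hyperparameters {sorted(unknown)}"
            )


@dataclass
class CvConfig:
    """Repeated stratified k-fold configuration (k * n_repeats iterations)."""

    k: int = 5
    n_repeats: int = 90
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def n_iterations(self) -> int:
        return self.k * self.n_repeats


def build_classifier(spec: ModelSpec):
    """Instantiate the scikit-learn estimator behind a ModelSpec.

    All models take the feature matrix as-is; the SVM relies on
    ``gamma='scale'`` for global scale adaptation. Per-feature
    standardization is deliberately not applied: on spectral matrices most
    columns carry only noise, and standardizing inflates them to unit
    variance, drowning the informative bands and degenerating the RBF
    kernel. The SVM exposes OvR decision-function scores; the ensembles
    expose vote fractions — both suffice for rank-based AUC.
    """
    hp = dict(spec.hyperparams)
    if spec.name == "extra_trees":
        return ExtraTreesClassifier(random_state=spec.seed, **hp)
    if spec.name == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    return SVC(
        decision_function_shape="ovr", random_state=spec.seed, **hp
    )


def _class_scores(clf, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """(n_samples, n_classes) ranking scores in ``classes`` column order."""
    if hasattr(clf, "predict_proba"):
        scores = clf.predict_proba(X)
    else:
        scores = clf.decision_function(X)
        if scores.ndim == 1:  # binary: one margin column
            scores = np.column_stack([-scores, scores])
    clf_classes = clf.classes_ if hasattr(clf, "classes_") else clf[-1].classes_
    out = np.full((X.shape[0], classes.size), -np.inf)
    for i, c in enumerate(clf_classes):
        j = np.searchsorted(classes, c)
        out[:, j] = scores[:, i]
    return out


def _binary_auc(y_pos: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    from scipy.stats import rankdata

    n_pos = int(y_pos.sum())
    n_neg = y_pos.size - n_pos
    ranks = rankdata(scores)
    return float(
        (ranks[y_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def ovr_metrics(
    y_true,
    y_pred,
    class_scores: np.ndarray | None = None,
    classes: Sequence | None = None,
) -> dict:
    """One-vs-rest metrics for one prediction round.

    Returns macro-averaged OvR accuracy / specificity / sensitivity (and
    AUC when ``class_scores`` is given), per-class tables, and the plain
    multiclass fraction-correct under ``"accuracy"``. Classes absent from
    ``y_true`` have undefined sensitivity; they are dropped from the macro
    averages with a :class:`DegenerateClassWarning`.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    else:
        classes = np.asarray(classes)
    n = y_true.size
    per_class: dict = {}
    accs, sps, ses, aucs = [], [], [], []
    for j, c in enumerate(classes):
        pos_true = y_true == c
        pos_pred = y_pred == c
        tp = int(np.sum(pos_true & pos_pred))
        fn = int(np.sum(pos_true & ~pos_pred))
        fp = int(np.sum(~pos_true & pos_pred))
        tn = n - tp - fn - fp
        entry = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
        entry["accuracy"] = (tp + tn) / n
        entry["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
        if tp + fn == 0:
            warnings.warn(
                f"class {c!r} absent from true labels; excluded from macro "
                "averages",
                DegenerateClassWarning,
                stacklevel=2,
            )
            entry["sensitivity"] = float("nan")
            per_class[c] = entry
            continue
        entry["sensitivity"] = tp / (tp + fn)
        accs.append(entry["accuracy"])
        sps.append(entry["specificity"])
        ses.append(entry["sensitivity"])
        if class_scores is not None and tn + fp > 0:
            auc = _binary_auc(pos_true, np.asarray(class_scores)[:, j])
            entry["auc"] = auc
            aucs.append(auc)
        per_class[c] = entry
    result = {
        "accuracy": float(np.mean(y_true == y_pred)),
        "ovr_accuracy": float(np.mean(accs)),
        "specificity": float(np.mean(sps)),
        "sensitivity": float(np.mean(ses)),
        "per_class": per_class,
    }
    if aucs:
        result["auc"] = float(np.mean(aucs))
    return result


@dataclass
class EvalReport:
    """Per-iteration and mean metrics of one (model, scenario) evaluation."""

    model: str
    scenario: str = ""
    n_iterations: int = 0
    iteration_metrics: list[dict] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    hyperparams: dict = field(default_factory=dict)

    @classmethod
    def from_iterations(
        cls, model: str, iterations: list[dict], scenario: str = "", **kw
    ) -> "EvalReport":
        keys = ("accuracy", "ovr_accuracy", "specificity", "sensitivity", "auc")
        means = {
            key: float(np.mean([m[key] for m in iterations if key in m]))
            for key in keys
            if any(key in m for m in iterations)
        }
        return cls(
            model=model,
            scenario=scenario,
            n_iterations=len(iterations),
            iteration_metrics=iterations,
            means=means,
            **kw,
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "scenario": self.scenario,
            "n_iterations": self.n_iterations,
            "means": self.means,
            "hyperparams": self.hyperparams,
        }


def _check_stratifiable(y: np.ndarray, k: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} samples; need >= {k} for "
            f"{k}-fold stratification"
        )


def evaluate_repeated_cv(
    X,
    y,
    model: ModelSpec | str,
    cv: CvConfig | None = None,
    scenario: str = "",
) -> EvalReport:
    """Score one model by repeated stratified k-fold cross-validation.

    Each repeat reshuffles the stratified partition (partition seeds
    derive from ``cv.seed``); every fold trains a fresh clone and tests on
    the held-out fold; per-iteration OvR metrics are averaged over all
    ``k * n_repeats`` iterations. Deterministic given (X, y, model, cv).
    """
    spec = ModelSpec(model) if isinstance(model, str) else model
    cv = cv or CvConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if cv.stratified:
        _check_stratifiable(y, cv.k)
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.k, n_repeats=cv.n_repeats, random_state=cv.seed
    )
    classes = np.unique(y)
    iterations = []
    for fold_i, (train, test) in enumerate(splitter.split(X, y)):
        clf = build_classifier(spec)
        try:
            clf.fit(X[train], y[train])
        except Exception as exc:
            raise type(exc)(f"fold {fold_i}: {exc}") from exc
        y_pred = clf.predict(X[test])
        scores = _class_scores(clf, X[test], classes)
        iterations.append(
            ovr_metrics(y[test], y_pred, class_scores=scores, classes=classes)
        )
    return EvalReport.from_iterations(
        spec.name,
        iterations,
        scenario=scenario,
        hyperparams=dict(spec.hyperparams),
    )


def grid_search(
    X,
    y,
    model_name: str,
    grid: Mapping[str, Sequence] | None = None,
    cv: CvConfig | None = None,
    model_seed: int = 0,
    n_jobs: int = 1,
) -> tuple[dict, EvalReport]:
    """Exhaustive hyperparameter search under the repeated-CV protocol.

    Every combination of the Cartesian product (keys enumerated in sorted
    order, values in listed order) is scored by
    :func:`evaluate_repeated_cv`; the combination with the highest mean
    fraction-correct wins, ties resolved by enumeration order.
    Combinations may be evaluated in parallel; the result is identical to
    serial execution because each evaluation is independently seeded and
    the reduction preserves enumeration order.
    """
    grid = dict(DEFAULT_GRIDS[model_name] if grid is None else grid)
    if model_name not in VALID_HYPERPARAMS:
        raise InvalidGrid(f"unknown model {model_name!r}")
    unknown = set(grid) - VALID_HYPERPARAMS[model_name]
    if unknown:
        raise InvalidGrid(
            f"{model_name} does not accept hyperparameters {sorted(unknown)}"
        )
    if not grid:
        raise InvalidGrid("grid must contain at least one hyperparameter")
    keys = sorted(grid)
    combos = [
        dict(zip(keys, values))
        for values in itertools.product(*(grid[k] for k in keys))
    ]
    cv = cv or CvConfig()
    reports = Parallel(n_jobs=n_jobs)(
        delayed(evaluate_repeated_cv)(
            X, y, ModelSpec(model_name, combo, seed=model_seed), cv
        )
        for combo in combos
    )
    best_i = 0
    for i, rep in enumerate(reports):
        if rep.means["accuracy"] > reports[best_i].means["accuracy"]:
            best_i = i
    return combos[best_i], reports[best_i]
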