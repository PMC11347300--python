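"""Classifier-based authentication evaluation.

The authentication decision is binary: did the evoked response come from the
enrolled user viewing their familiar face (*target*, the positive class) or
not (*nontarget*)?  Five classifiers are supported — linear SVM (LSVM),
quadratic discriminant analysis (QDA), Gaussian Naive Bayes (NB), logistic
regression (LR) and RBF-kernel SVM (RBF-SVM) — each evaluated with
stratified 5-fold cross-validation.  Feature columns are z-scored inside
each training fold only, so no information leaks from test folds.

Metrics (pooled confusion counts across folds):

* ``accuracy % = 100 * (TP + TN) / (TP + FN + TN + FP)`` — the headline
  accuracy is the mean of per-fold accuracies;
* ``FAR = FP / (FP + TN)`` — impostor acceptance (nontarget misread as the
  user's response);
* ``FRR = FN / (FN + TP)`` — genuine-user rejection;
* AUC from the pooled decision scores.

``trial_sweep`` re-averages epochs from only the first *n* trials (keeping
the 1 target : 9 nontarget ratio) to chart how authentication accuracy
degrades as the enrolment task is shortened.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, DataError
from .features import DEFAULT_WINDOWS, build_feature_table, feature_columns
from .preprocess import PreprocessConfig, average_epochs, preprocess_subject
from .synth import SubjectRecording

__all__ = [
    "CLASSIFIERS",
    "ConfusionCounts",
    "ClassificationReport",
    "SweepResult",
    "make_classifier",
    "metrics_from_counts",
    "crossval_evaluate",
    "trial_sweep",
]

log = logging.getLogger(__name__)

CLASSIFIERS = ("LSVM", "QDA", "NB", "LR", "RBF-SVM")

POSITIVE = "target"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class ClassificationReport:
    """Cross-validated authentication metrics for one classifier."""

    classifier_name: str
    accuracy: float  # fold-mean accuracy, percent (headline)
    pooled_accuracy: float  # percent, from pooled counts
    auc: float
    far: float
    frr: float
    counts: ConfusionCounts
    per_fold: list[ConfusionCounts]
    fold_accuracies: list[float]
    n_folds: int
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier_name,
            "accuracy_pct": self.accuracy,
            "pooled_accuracy_pct": self.pooled_accuracy,
            "auc": self.auc,
            "far": self.far,
            "frr": self.frr,
            "counts": {"TP": self.counts.tp, "FN": self.counts.fn,
                       "TN": self.counts.tn, "FP": self.counts.fp},
            "n_folds": self.n_folds,
            "seed": self.seed,
            "hyperparameters": self.hyperparameters,
        }


@dataclass(frozen=True)
class SweepResult:
    n_trials: int
    report: ClassificationReport


def make_classifier(name: str, seed: int = 0) -> Pipeline:
    """A fresh scaler+classifier pipeline for one of the supported names."""
    clfs = {
        "LSVM": lambda: SVC(kernel="linear", random_state=seed),
        "QDA": lambda: QuadraticDiscriminantAnalysis(),
        "NB": lambda: GaussianNB(),
        "LR": lambda: LogisticRegression(max_iter=1000, random_state=seed),
        "RBF-SVM": lambda: SVC(kernel="rbf", random_state=seed),
    }
    if name not in clfs:
        raise ConfigError(f"unknown classifier {name!r}; supported: {CLASSIFIERS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clfs[name]())])


def metrics_from_counts(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy %, FAR, FRR) from confusion counts.

    accuracy on the 0-100 scale; FAR = FP/(FP+TN); FRR = FN/(FN+TP).
    """
    if counts.total == 0:
        raise DataError("empty confusion counts: total denominator is zero")
    if counts.fp + counts.tn == 0:
        raise DataError("no nontarget samples: FAR denominator (FP+TN) is zero")
    if counts.fn + counts.tp == 0:
        raise DataError("no target samples: FRR denominator (FN+TP) is zero")
    accuracy = 100.0 * (counts.tp + counts.tn) / counts.total
    far = counts.fp / (counts.fp + counts.tn)
    frr = counts.fn / (counts.fn + counts.tp)
    return accuracy, far, frr


def _scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        try:
            return np.asarray(model.decision_function(X))
        except AttributeError:
            pass
    return np.asarray(model.predict_proba(X))[:, 1]


def crossval_evaluate(
    features: pd.DataFrame | np.ndarray,
    labels,
    classifier_name: str,
    k: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold evaluation of one classifier.

    ``features`` may be a feature table (its ``subject``/``condition``
    columns are dropped) or a plain array; ``labels`` are
    ``"target"``/``"nontarget"`` strings or a boolean/0-1 array with 1 =
    target.  Fitting — including the feature z-scoring — happens on the
    training fold only.  Confusion counts are pooled across folds; the
    headline accuracy is the fold mean.
    """
    if isinstance(features, pd.DataFrame):
        X = features[feature_columns(features)].to_numpy(float)
    else:
        X = np.asarray(features, float)
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = (y == POSITIVE).astype(int)
    else:
        y = y.astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise DataError(f"need exactly 2 classes, got {classes.tolist()}")
    if counts.min() < k:
        raise DataError(f"each class needs >= k={k} members, got counts {counts.tolist()}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[ConfusionCounts] = []
    fold_acc: list[float] = []
    all_scores = np.empty_like(y, dtype=float)
    for train, test in skf.split(X, y):
        model = make_classifier(classifier_name, seed)
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        yt = y[test]
        c = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (yt == 1))),
            fn=int(np.sum((pred == 0) & (yt == 1))),
            tn=int(np.sum((pred == 0) & (yt == 0))),
            fp=int(np.sum((pred == 1) & (yt == 0))),
        )
        per_fold.append(c)
        fold_acc.append(100.0 * (c.tp + c.tn) / c.total)
        all_scores[test] = _scores(model, X[test])

    pooled = sum(per_fold, ConfusionCounts())
    pooled_acc, far, frr = metrics_from_counts(pooled)
    auc = float(roc_auc_score(y, all_scores))
    hp = {key: repr(v) for key, v in make_classifier(classifier_name, seed)
          .named_steps["clf"].get_params().items()}
    return ClassificationReport(
        classifier_name=classifier_name,
        accuracy=float(np.mean(fold_acc)),
        pooled_accuracy=pooled_acc,
        auc=auc,
        far=far,
        frr=frr,
        counts=pooled,
        per_fold=per_fold,
        fold_accuracies=fold_acc,
        n_folds=k,
        seed=seed,
        hyperparameters=hp,
    )


def trial_sweep(
    recordings: list[SubjectRecording],
    config: PreprocessConfig | None = None,
    n_trials_list: list[int] | None = None,
    classifier_name: str = "QDA",
    seed: int = 0,
    modality: str = "ErPR",
    k: int = 5,
) -> list[SweepResult]:
    """Authentication accuracy as a function of the number of RSVP trials.

    For each ``n`` in ``n_trials_list`` the per-subject averages are rebuilt
    from the first ``n`` trials' epochs only (each trial contributes 1 target
    and 9 nontarget epochs, preserving the 1:9 ratio), the feature table is
    rebuilt, and the classifier is re-evaluated.  Values of ``n`` for which
    the ratio is not representable are skipped with a warning.
    """
    config = PreprocessConfig() if config is None else config
    cfg = recordings[0].config
    if n_trials_list is None:
        n_trials_list = list(range(5, cfg.n_trials + 1, 5))
    epoch_sets = {
        rec.subject_id: preprocess_subject(rec, config, average=False)[modality]
        for rec in recordings
    }
    results: list[SweepResult] = []
    for n in sorted(n_trials_list):
        if n < 1 or n > cfg.n_trials:
            log.warning("skipping n_trials=%d (task has %d trials)", n, cfg.n_trials)
            continue
        averages = {}
        try:
            for sid, es in epoch_sets.items():
                subset = [e for e in es.epochs if 0 <= e.trial < n]
                averages[sid] = average_epochs(subset)
        except DataError as err:
            log.warning("skipping n_trials=%d: %s", n, err)
            continue
        table = build_feature_table(averages, DEFAULT_WINDOWS)
        report = crossval_evaluate(table, table["condition"].to_numpy(), classifier_name,
                                   k=k, seed=seed)
        results.append(SweepResult(n_trials=n, report=report))
    return results
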