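"""Confusion-matrix metrics and cross-validation harnesses.

Five metrics summarize binary site prediction: accuracy, recall
(sensitivity), precision, Matthews correlation coefficient and F-measure
(the harmonic mean of precision and recall, used throughout the package as
the fitness score for feature selection and hyperparameter tuning).

Zero-denominator conventions (fixed and unit-tested): precision, recall and
F-measure are 0 when their denominator is empty; MCC is 0 when any marginal
of the confusion table is empty.

Cross-validation uses stratified folds with seeded shuffling; metrics are
computed on the pooled out-of-fold predictions by default (one confusion
table over all folds — well-defined for MCC even with small folds), with
per-fold bundles also returned so macro-averages can be formed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = ("accuracy", "recall", "precision", "mcc", "f_measure")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricsBundle:
    accuracy: float
    recall: float
    precision: float
    mcc: float
    f_measure: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


def compute_metrics(c: ConfusionCounts) -> MetricsBundle:
    """Evaluate the five confusion-based metrics.

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); the other
    four are the usual ratio definitions.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    accuracy = (tp + tn) / c.total
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f_measure = (2 * precision * recall / (precision + recall)
                 if precision + recall else 0.0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsBundle(accuracy, recall, precision, mcc, f_measure)


def default_classifier(seed: int = 0, **overrides):
    """The package's default classifier: a 100-iteration LightGBM model."""
    from lightgbm import LGBMClassifier

    params = dict(n_estimators=100, random_state=seed, verbose=-1,
                  deterministic=True, force_row_wise=True, n_jobs=1)
    params.update(overrides)
    return LGBMClassifier(**params)


@dataclass(frozen=True)
class CVResult:
    pooled: MetricsBundle
    macro: MetricsBundle
    per_fold: tuple[MetricsBundle, ...]
    confusion: ConfusionCounts


def cross_validate(X, y, classifier=None, k: int = 10, seed: int = 0,
                   aggregate: str = "pooled") -> CVResult:
    """Stratified k-fold CV of a scikit-learn-style classifier.

    The estimator is cloned per fold so each fold trains from scratch. The
    returned :class:`CVResult` carries the pooled bundle (confusion table
    over all out-of-fold predictions), the macro bundle (mean of per-fold
    metrics) and the per-fold bundles; ``aggregate`` only flags which of the
    two is the headline mode for callers that want a single bundle.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if aggregate not in ("pooled", "macro"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got classes {classes}")
    if counts.min() < k:
        raise ValueError(
            f"k={k} exceeds the minority-class count {counts.min()}"
        )
    if classifier is None:
        classifier = default_classifier()

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty_like(y)
    per_fold: list[MetricsBundle] = []
    for train_idx, test_idx in skf.split(X, y):
        model = clone(classifier)
        model.fit(X[train_idx], y[train_idx])
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper invents Column_i names when fit on a
            # bare array and then complains at predict time; pure noise here
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names")
            pred = np.asarray(model.predict(X[test_idx]), dtype=int)
        oof[test_idx] = pred
        per_fold.append(compute_metrics(
            ConfusionCounts.from_predictions(y[test_idx], pred)))

    confusion = ConfusionCounts.from_predictions(y, oof)
    pooled = compute_metrics(confusion)
    macro = MetricsBundle(*(
        float(np.mean([b[m] for b in per_fold])) for m in METRIC_NAMES
    ))
    return CVResult(pooled=pooled, macro=macro, per_fold=tuple(per_fold),
                    confusion=confusion)


@dataclass(frozen=True)
class RepeatedCVSummary:
    """Stability summary of repeated seeded cross-validation.

    ``per_repeat`` holds one metrics bundle per seed; ``mean``/``std``/
    ``max`` summarize each metric over the repeats (std is the population
    standard deviation). The per-repeat values are retained so histograms
    of the fitness distribution can be exported.
    """

    seeds: tuple[int, ...]
    per_repeat: tuple[MetricsBundle, ...]
    mean: MetricsBundle
    std: MetricsBundle
    max: MetricsBundle

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)


def repeated_cv(X, y, classifier=None, n_repeats: int = 100, k: int = 10,
                seeds=None, aggregate: str = "pooled") -> RepeatedCVSummary:
    """Repeat k-fold CV under different fold-shuffling seeds.

    ``seeds`` defaults to 0..n_repeats−1; duplicates are rejected because
    they would silently understate the variance.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    seeds = [int(s) for s in seeds]
    if len(seeds) != n_repeats:
        raise ValueError("len(seeds) must equal n_repeats")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds in repeated CV")

    bundles: list[MetricsBundle] = []
    for s in seeds:
        res = cross_validate(X, y, classifier=classifier, k=k, seed=s)
        bundles.append(res.pooled if aggregate == "pooled" else res.macro)

    def summarize(fn) -> MetricsBundle:
        return MetricsBundle(*(float(fn([b[m] for b in bundles]))
                               for m in METRIC_NAMES))

    return RepeatedCVSummary(
        seeds=tuple(seeds),
        per_repeat=tuple(bundles),
        mean=summarize(np.mean),
        std=summarize(np.std),
        max=summarize(np.max),
    )


def write_metrics_tsv(bundles, path, row_names=None) -> None:
    """Write metric bundles as a TSV mirroring the standard table columns."""
    import pandas as pd

    rows = [b.as_dict() for b in bundles]
    df = pd.DataFrame(rows)[list(METRIC_NAMES)]
    df.columns = ["ACC", "Recall", "Precision", "MCC", "F-measure"]
    if row_names is not None:
        df.insert(0, "name", list(row_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
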