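"""Confusion-matrix metrics, jackknife cross-validation, independent tests.

The positive class is ``trans`` throughout, so sensitivity (Sn) is the
true-positive rate on trans-Golgi proteins and specificity (Sp) the
true-negative rate on cis-Golgi proteins. Jackknife cross-validation is
leave-one-out: every sample is held out exactly once and the per-fold
predictions are pooled into a single confusion matrix (with one-sample test
folds, pooling is the only well-defined aggregation). MCC with a zero
denominator factor is defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .balancing import SmoteConfig, smote_balance
from .io import FeatureMatrix
from .model import RfConfig, TrainedModel, predict, train

POSITIVE_LABEL = "trans"


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.total < 1:
            raise EvaluationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_labels(y_true, y_pred, positive: str = POSITIVE_LABEL) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        if y_true.shape != y_pred.shape:
            raise EvaluationError("label vectors differ in length")
        t = y_true == positive
        p = y_pred == positive
        return ConfusionCounts(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    sn: float
    sp: float
    mcc: float
    counts: ConfusionCounts
    protocol: str  # "jackknife" | "independent"

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "protocol": self.protocol,
            "counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "mcc": self.mcc,
        }


def compute_metrics(counts: ConfusionCounts, protocol: str = "independent") -> MetricsReport:
    """ACC, Sn, Sp and MCC from pooled confusion counts.

    ACC = (TP+TN)/N; Sn = TP/(TP+FN); Sp = TN/(TN+FP);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP)).
    An undefined ratio (zero denominator) is reported as 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(acc=acc, sn=sn, sp=sp, mcc=mcc, counts=counts, protocol=protocol)


def jackknife(
    matrix: FeatureMatrix,
    rf_config: RfConfig | None = None,
    smote: SmoteConfig | None = None,
) -> MetricsReport:
    """Leave-one-out evaluation of a random forest on a labeled matrix.

    For each of the T samples a forest is trained on the other T-1 (with the
    fold index added to the seed, so one integer reproduces the whole run)
    and the held-out sample predicted; counts are pooled. If ``smote`` is
    given, SMOTE is applied *inside* each training fold (leakage-safe mode)
    rather than to the full matrix beforehand.

    A fold whose training part loses a class entirely is still run; the
    forest then trains on the remaining class distribution.
    """
    if rf_config is None:
        rf_config = RfConfig()
    y = matrix.label_array()
    if len(set(y.tolist())) != 2:
        raise EvaluationError("jackknife needs a two-class matrix")
    T = matrix.n_samples
    preds = []
    for i in range(T):
        rest = [j for j in range(T) if j != i]
        fold = matrix.select_samples(rest)
        fold_counts = [fold.labels.count(c) for c in set(fold.labels)]
        if smote is not None and len(fold_counts) == 2 and min(fold_counts) >= 2:
            fold = smote_balance(
                fold, SmoteConfig(k_neighbors=smote.k_neighbors, seed=smote.seed + i)
            )
        cfg = RfConfig(
            n_trees=rf_config.n_trees,
            max_features=rf_config.max_features,
            seed=rf_config.seed + i,
            max_depth=rf_config.max_depth,
            min_samples_leaf=rf_config.min_samples_leaf,
            criterion=rf_config.criterion,
        )
        if len(set(fold.labels)) < 2:
            # degenerate fold: predict the only remaining class
            preds.append(fold.labels[0])
            continue
        model = train(fold, cfg)
        preds.append(predict(model, matrix.select_samples([i]))[0])
    counts = ConfusionCounts.from_labels(y, preds)
    return compute_metrics(counts, protocol="jackknife")


def independent_test(model: TrainedModel, matrix: FeatureMatrix) -> MetricsReport:
    """Single-pass evaluation of a trained model on a held-out labeled set.

    The test set is never balanced or re-encoded with training statistics;
    columns are aligned to the model by name.
    """
    if matrix.n_samples == 0:
        raise EvaluationError("empty test matrix")
    y = matrix.label_array()
    preds = predict(model, matrix)
    counts = ConfusionCounts.from_labels(y, preds)
    return compute_metrics(counts, protocol="independent")
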