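"""Random-forest classifier with a fixed-seed, name-aligned contract.

A thin, reproducibility-focused layer over scikit-learn's
``RandomForestClassifier``: training is deterministic given the seed,
prediction aligns feature columns by name (so column permutations are
harmless and silent feature mismatches impossible), ties in the forest vote
go to the positive class (``trans``), and per-feature importances (mean
impurity decrease, normalised to sum 1) are first-class output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .io import FeatureMatrix

_FORMAT = "subgolgi-rf"
_FORMAT_VERSION = 1


class ModelError(ValueError):
    """Raised on training/prediction contract violations."""


class ModelFormatError(ValueError):
    """Raised when a saved model file cannot be understood."""


@dataclass(frozen=True)
class RfConfig:
    """Forest hyperparameters.

    n_trees=500 and sqrt feature subsampling give stable impurity-based
    importances on feature sets up to a few hundred columns; all knobs are
    exposed for smaller/faster runs.
    """

    n_trees: int = 500
    max_features: str = "sqrt"  # "sqrt" or "all"
    seed: int = 0
    max_depth: int | None = None
    min_samples_leaf: int = 1
    criterion: str = "gini"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features not in ("sqrt", "all"):
            raise ValueError("max_features must be 'sqrt' or 'all'")


class GolgiForestClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn style random forest for cis/trans discrimination.

    ``predict`` breaks 50/50 forest votes toward ``positive_label``
    (deterministic tie rule). Fitted attributes: ``classes_``,
    ``feature_importances_``, ``forest_``.
    """

    def __init__(
        self,
        n_trees: int = 500,
        max_features: str = "sqrt",
        seed: int = 0,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        criterion: str = "gini",
        positive_label: str = "trans",
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.criterion = criterion
        self.positive_label = positive_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if len(set(y.tolist())) < 2:
            raise ModelError("training data contains a single class")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt" if self.max_features == "sqrt" else None,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            criterion=self.criterion,
            random_state=self.seed,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_importances_ = self.forest_.feature_importances_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        proba = self.predict_proba(X)
        if self.positive_label in self.classes_:
            pos_idx = int(np.where(self.classes_ == self.positive_label)[0][0])
            pos = proba[:, pos_idx]
            other = self.classes_[1 - pos_idx] if len(self.classes_) == 2 else None
            return np.where(pos >= 0.5, self.positive_label, other).astype(object)
        return self.forest_.predict(np.asarray(X, dtype=float))


@dataclass
class TrainedModel:
    """A fitted forest bound to its feature-name order and config."""

    estimator: GolgiForestClassifier
    feature_names: list[str]
    config: RfConfig
    positive_label: str = "trans"
    importances: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.estimator.feature_importances_, dtype=float)
        if len(self.feature_names) != self.importances.size:
            raise ModelError("feature_names / importances length mismatch")

    @property
    def classes(self) -> list[str]:
        return list(self.estimator.classes_)


def train(matrix: FeatureMatrix, config: RfConfig | None = None) -> TrainedModel:
    """Fit a random forest on a labeled feature matrix.

    Deterministic given ``config.seed``. Importances are the forest's mean
    impurity decrease, normalised to sum 1.
    """
    if config is None:
        config = RfConfig()
    y = matrix.label_array()
    est = GolgiForestClassifier(
        n_trees=config.n_trees,
        max_features=config.max_features,
        seed=config.seed,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        criterion=config.criterion,
    ).fit(matrix.values, y)
    return TrainedModel(estimator=est, feature_names=list(matrix.feature_names), config=config)


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Predict labels for a matrix, aligning columns to the model by name."""
    if set(matrix.feature_names) != set(model.feature_names):
        missing = sorted(set(model.feature_names) - set(matrix.feature_names))
        extra = sorted(set(matrix.feature_names) - set(model.feature_names))
        raise ModelError(
            f"feature-name mismatch: missing {missing[:5]}{'...' if len(missing) > 5 else ''}, "
            f"unexpected {extra[:5]}{'...' if len(extra) > 5 else ''}"
        )
    aligned = matrix.select_features(model.feature_names)
    return model.estimator.predict(aligned.values)


def save(model: TrainedModel, path: str | Path) -> None:
    """Serialise a model bundle (self-describing: format, version, config)."""
    bundle = {
        "format": _FORMAT,
        "version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "feature_names": model.feature_names,
        "positive_label": model.positive_label,
        "importances": model.importances,
        "estimator": model.estimator,
    }
    joblib.dump(bundle, path)


def load(path: str | Path) -> TrainedModel:
    try:
        bundle = joblib.load(path)
    except Exception as exc:  # corrupted / not a joblib file
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(bundle, dict) or bundle.get("format") != _FORMAT:
        raise ModelFormatError(f"{path} is not a {_FORMAT} model bundle")
    if bundle.get("version") != _FORMAT_VERSION:
        raise ModelFormatError(
            f"model version {bundle.get('version')} != supported {_FORMAT_VERSION}"
        )
    model = TrainedModel(
        estimator=bundle["estimator"],
        feature_names=list(bundle["feature_names"]),
        config=RfConfig(**bundle["config"]),
        positive_label=bundle["positive_label"],
    )
    model.importances = np.asarray(bundle["importances"], dtype=float)
    return model
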