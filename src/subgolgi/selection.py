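"""Univariate ANOVA F-score feature ranking for two-class data.

Each feature is scored with the one-way ANOVA F statistic — between-group
mean square over within-group mean square (df 1 and N-2 for two groups).
Larger F means the feature separates the classes better relative to its
within-class spread; for two groups F equals the square of the pooled
two-sample t statistic.

Degenerate features are given sentinels rather than epsilon-adjusted scores:
zero within-group variance with distinct group means scores +inf (a
perfectly separating feature always ranks first); a globally constant
feature scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FeatureMatrix


class SelectionError(ValueError):
    """Raised on invalid ranking/selection inputs."""


def anova_f_score(group_a, group_b) -> float:
    """One-way ANOVA F statistic for two groups of scalar observations.

    Both groups need at least 2 samples. Returns MSB / MSW where MSB is the
    between-group sum of squares (df = 1) and MSW the pooled within-group
    mean square (df = N - 2). Zero MSW yields +inf when the group means
    differ and 0.0 when they do not.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SelectionError(
            f"each group needs >= 2 samples (got {a.size} and {b.size})"
        )
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    msb = ssb  # df = G - 1 = 1
    msw = ssw / (n - 2)
    if msw == 0.0:
        return float("inf") if msb > 0.0 else 0.0
    return float(msb / msw)


@dataclass
class FeatureRanking:
    """ANOVA scores sorted by F descending; ties keep original column order."""

    entries: list[tuple[str, float]]
    group_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def top(self, n: int) -> list[str]:
        return self.feature_names[:n]

    def __len__(self) -> int:
        return len(self.entries)


def rank_features(matrix: FeatureMatrix) -> FeatureRanking:
    """Score every column of a two-class labeled matrix and sort by F.

    Ordering is deterministic: F descending, ties broken by original column
    index (stable). Requires exactly two label values with >= 2 samples each.
    """
    y = matrix.label_array()
    classes = sorted(set(y))
    if len(classes) != 2:
        raise SelectionError(f"expected exactly 2 classes, got {classes}")
    mask = y == classes[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise SelectionError("each class needs >= 2 samples")
    scores = [
        anova_f_score(matrix.values[mask, j], matrix.values[~mask, j])
        for j in range(matrix.n_features)
    ]
    order = sorted(range(matrix.n_features), key=lambda j: (-scores[j], j))
    return FeatureRanking(
        entries=[(matrix.feature_names[j], scores[j]) for j in order],
        group_sizes={c: int((y == c).sum()) for c in classes},
    )


def select_top(matrix: FeatureMatrix, ranking: FeatureRanking, n: int) -> FeatureMatrix:
    """Return the ``n`` top-ranked columns (sample order and labels kept)."""
    if not 1 <= n <= matrix.n_features:
        raise SelectionError(
            f"n={n} out of range [1, {matrix.n_features}]"
        )
    return matrix.select_features(ranking.top(n))


class AnovaTopN(BaseEstimator, TransformerMixin):
    """scikit-learn transformer keeping the n features with highest ANOVA F.

    Fitted attributes: ``scores_`` (per input column), ``ranking_``
    (column indices sorted by the tie-stable F order) and
    ``selected_indices_``.
    """

    def __init__(self, n: int = 10):
        self.n = n

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = sorted(set(y.tolist()))
        if len(classes) != 2:
            raise SelectionError(f"expected exactly 2 classes, got {classes}")
        mask = y == classes[0]
        self.scores_ = np.array(
            [anova_f_score(X[mask, j], X[~mask, j]) for j in range(X.shape[1])]
        )
        self.ranking_ = np.array(
            sorted(range(X.shape[1]), key=lambda j: (-self.scores_[j], j))
        )
        if not 1 <= self.n <= X.shape[1]:
            raise SelectionError(f"n={self.n} out of range [1, {X.shape[1]}]")
        self.selected_indices_ = self.ranking_[: self.n]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.selected_indices_]
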