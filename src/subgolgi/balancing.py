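"""SMOTE class balancing: synthesize minority samples by interpolation.

The minority class is brought up to the majority size by drawing synthetic
points z = x + u * (x' - x), with x a minority row, x' one of its k nearest
minority neighbours (Euclidean distance, k = 5 by default) and u uniform on
[0, 1]. Synthetic points therefore lie on segments between minority
neighbours — inside the minority convex hull — rather than duplicating rows.

Original rows are preserved verbatim, in input order, ahead of the synthetic
block; the whole operation is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .io import FeatureMatrix

logger = logging.getLogger(__name__)


class BalancingError(ValueError):
    """Raised when oversampling preconditions fail."""


@dataclass(frozen=True)
class SmoteConfig:
    """k_neighbors: neighbourhood size for interpolation partners;
    target="parity" balances the minority up to the majority count."""

    k_neighbors: int = 5
    seed: int = 0
    target: str = "parity"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target != "parity":
            raise ValueError(f"unsupported target: {self.target!r}")


class Smote(BaseEstimator):
    """Minimal SMOTE oversampler with a ``fit_resample`` interface.

    Operates on arrays; :func:`smote_balance` wraps it for
    :class:`~subgolgi.io.FeatureMatrix` inputs.
    """

    def __init__(self, k_neighbors: int = 5, seed: int = 0):
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise BalancingError(f"expected exactly 2 classes, got {list(classes)}")
        if counts[0] == counts[1]:
            return X.copy(), y.copy()
        minority = classes[int(np.argmin(counts))]
        majority_n = int(counts.max())
        min_mask = y == minority
        X_min = X[min_mask]
        n_min = X_min.shape[0]
        if n_min < 2:
            raise BalancingError(
                f"minority class {minority!r} has {n_min} sample(s); need >= 2"
            )
        k = self.k_neighbors
        if k >= n_min:
            k = n_min - 1
            logger.warning(
                "k_neighbors=%d >= minority count %d; reduced to %d",
                self.k_neighbors, n_min, k,
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        # first neighbour is the point itself (distance 0)
        neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]

        rng = np.random.default_rng(self.seed)
        n_synth = majority_n - n_min
        base = rng.integers(0, n_min, size=n_synth)
        partner = neigh[base, rng.integers(0, k, size=n_synth)]
        u = rng.random(size=n_synth)
        synth = X_min[base] + u[:, None] * (X_min[partner] - X_min[base])

        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_synth, minority, dtype=object)])
        return X_out, y_out


def smote_balance(matrix: FeatureMatrix, config: SmoteConfig | None = None) -> FeatureMatrix:
    """Balance a two-class labeled matrix to parity with SMOTE.

    Output keeps every original row first (bit-identical, input order) and
    appends synthetic minority rows with ids ``smote_0``, ``smote_1``, ...
    Already-balanced input is returned unchanged (as a copy).
    """
    if config is None:
        config = SmoteConfig()
    y = matrix.label_array()
    X_out, y_out = Smote(k_neighbors=config.k_neighbors, seed=config.seed).fit_resample(
        matrix.values, y
    )
    n_synth = X_out.shape[0] - matrix.n_samples
    ids = list(matrix.sample_ids) + [f"smote_{i}" for i in range(n_synth)]
    return FeatureMatrix(
        sample_ids=ids,
        feature_names=list(matrix.feature_names),
        values=X_out,
        labels=list(y_out),
    )
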