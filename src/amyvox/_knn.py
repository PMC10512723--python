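"""Deterministic K-nearest-neighbor voting classifier.

Euclidean distance; distance ties broken by smaller training-row index
(stable argsort); even vote splits are classified positive (score >= 0.5).
Callers are responsible for column scaling.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


class KNNVote:
    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNVote":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self._X, self._y = X, y
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class vote fraction among the k nearest training rows."""
        if self._X is None:
            raise RuntimeError("fit first")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = min(self.k, len(self._X))
        d = cdist(X, self._X)
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        return self._y[order].mean(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)
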