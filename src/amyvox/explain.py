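"""Exact Shapley attribution by coalition enumeration.

The value function is interventional: v(S) is the mean model score over
background rows with the features in S replaced by the explained subject's
values. Exact enumeration is feasible because the selected feature count is
small (guarded at 20).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from math import factorial

import numpy as np
import pandas as pd

from . import model_zoo
from .model_zoo import ModelSpec

__all__ = ["ShapExplanation", "exact_shap", "explain_cohort"]

MAX_FEATURES = 20


@dataclass(frozen=True)
class ShapExplanation:
    subject_id: str
    base_value: float
    attributions: np.ndarray
    model_score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributions", np.asarray(self.attributions, dtype=float))
        if abs(self.base_value + self.attributions.sum() - self.model_score) > 1e-8:
            raise ValueError("efficiency violated: base + sum(attributions) != score")


def _coalition_values(score_fn, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    """v(S) for every coalition bitmask S, batched over one score_fn call."""
    m = len(x)
    n_bg = len(background)
    n_masks = 1 << m
    values = np.empty(n_masks)
    chunk = max(1, min(n_masks, 2_000_000 // max(n_bg * m, 1)))
    for start in range(0, n_masks, chunk):
        masks = np.arange(start, min(start + chunk, n_masks))
        rows = np.repeat(background[None, :, :], len(masks), axis=0)  # (masks, bg, m)
        for j in range(m):
            has_j = (masks >> j) & 1 == 1
            rows[has_j, :, j] = x[j]
        flat = np.asarray(score_fn(rows.reshape(len(masks) * n_bg, m)), dtype=float)
        values[masks] = flat.reshape(len(masks), n_bg).mean(axis=1)
    return values


def exact_shap(
    score_fn,
    background: np.ndarray,
    x: np.ndarray,
    subject_id: str = "",
) -> ShapExplanation:
    """Exact Shapley attributions of ``score_fn`` at ``x``.

    attribution_j = sum over S not containing j of
    |S|! (M - |S| - 1)! / M! * (v(S u {j}) - v(S)).
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    m = len(x)
    if m > MAX_FEATURES:
        raise ValueError(
            f"{m} features exceeds the enumeration guard ({MAX_FEATURES}); "
            "reduce the feature set first"
        )
    if background.size == 0:
        raise ValueError("background must be nonempty")
    if background.shape[1] != m:
        raise ValueError("background width must match len(x)")

    v = _coalition_values(score_fn, background, x)
    weights = np.array(
        [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
    )
    masks = np.arange(1 << m)
    sizes = np.array([bin(mask).count("1") for mask in masks])
    attributions = np.empty(m)
    for j in range(m):
        without_j = masks[(masks >> j) & 1 == 0]
        gain = v[without_j | (1 << j)] - v[without_j]
        attributions[j] = float(np.sum(weights[sizes[without_j]] * gain))
    base = float(v[0])
    score = float(v[-1])
    return ShapExplanation(subject_id, base, attributions, score)


def explain_cohort(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    selected: list[int],
    seed: int = 0,
    names: list[str] | None = None,
) -> tuple[list[ShapExplanation], pd.DataFrame]:
    """Leave-one-out attribution of every subject's held-out prediction.

    For each subject the model is refitted on the remaining rows, which also
    serve as the background set. Returns per-subject explanations and a
    global importance table ordered by mean |attribution|, with the sign
    summary being the correlation between feature value and attribution.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))[:, np.asarray(selected, dtype=int)]
    y = np.asarray(y, dtype=int)
    n, m = X.shape
    if m > MAX_FEATURES:
        raise ValueError(f"{m} selected features exceeds the enumeration guard")
    if names is None:
        names = [f"f{j}" for j in selected]
    spec = dc_replace(spec, seed=seed)

    explanations: list[ShapExplanation] = []
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        model = model_zoo.fit(spec, X[rest], y[rest])
        expl = exact_shap(
            model_zoo.score_function(model), X[rest], X[i], subject_id=f"S{i + 1:03d}"
        )
        explanations.append(expl)

    attr = np.vstack([e.attributions for e in explanations])
    mean_abs = np.abs(attr).mean(axis=0)
    corr = np.empty(m)
    for j in range(m):
        xj, aj = X[:, j], attr[:, j]
        if np.std(xj) == 0 or np.std(aj) == 0:
            corr[j] = 0.0
        else:
            corr[j] = float(np.corrcoef(xj, aj)[0, 1])
    importance = (
        pd.DataFrame(
            {"feature": names, "mean_abs_attribution": mean_abs, "value_attribution_corr": corr}
        )
        .sort_values("mean_abs_attribution", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return explanations, importance
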