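"""Goodness-of-fit machinery: LOOCV and bootstrap-nested LOOCV.

The bootstrap-nested scheme redraws each leave-one-out training fold with
replacement (size n-1) before fitting, repeats the full LOOCV pass B times,
and summarizes each metric's B-length distribution by its mean and
2.5/97.5 percentile confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.stats import rankdata

from . import model_zoo
from .model_zoo import ModelSpec

__all__ = [
    "PredictionSet",
    "MetricDistribution",
    "METRICS",
    "compute_metrics",
    "loocv",
    "bootstrap_loocv",
    "run_study",
]

METRICS = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass(frozen=True)
class PredictionSet:
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    iteration: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("y_true", "y_pred", "scores"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.y_true)
        if len(self.y_pred) != n or len(self.scores) != n:
            raise ValueError("prediction arrays must have one entry per subject")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")


@dataclass(frozen=True)
class MetricDistribution:
    name: str
    values: np.ndarray
    mean: float
    lo: float
    hi: float

    @classmethod
    def from_values(cls, name: str, values: np.ndarray) -> "MetricDistribution":
        values = np.asarray(values, dtype=float)
        return cls(
            name=name,
            values=values,
            mean=float(values.mean()),
            lo=float(np.percentile(values, 2.5)),
            hi=float(np.percentile(values, 97.5)),
        )


def _auc_midrank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    ranks = rankdata(scores)  # midranks
    rank_sum = float(ranks[y_true == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(pred: PredictionSet) -> dict[str, float]:
    """Accuracy, precision, recall, F1 (positive class) and midrank AUC."""
    y, yhat, s = pred.y_true, pred.y_pred, pred.scores
    if len(np.unique(y)) < 2:
        raise ValueError("true labels contain a single class")
    tp = int(((y == 1) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    accuracy = (tp + tn) / len(y)
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {
        "accuracy": float(accuracy),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "auc": float(_auc_midrank(y, s)),
    }


def loocv(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0) -> PredictionSet:
    """Leave-one-out: each subject predicted by a model fitted on the rest."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("need n >= 3 for LOOCV")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    spec = dc_replace(spec, seed=seed)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        if len(np.unique(y[rest])) < 2:
            raise ValueError("training fold contains a single class")
        model = model_zoo.fit(spec, X[rest], y[rest])
        s, lab = model_zoo.predict(model, X[i : i + 1])
        scores[i], preds[i] = s[0], lab[0]
    return PredictionSet(y, preds, scores, seed=seed)


def bootstrap_loocv(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    B: int = 5000,
    seed: int = 0,
    identity_resample: bool = False,
) -> dict[str, MetricDistribution]:
    """B bootstrap-nested LOOCV passes -> per-metric distributions.

    Inside each pass, every leave-one-out training fold is replaced by a
    with-replacement resample of itself (size n-1, redrawn until both
    classes are present). ``identity_resample`` is a test hook that uses the
    fold unchanged, making one pass identical to :func:`loocv`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = len(y)
    if B < 1:
        raise ValueError("B must be >= 1")
    spec = dc_replace(spec, seed=seed)
    values = {m: np.empty(B) for m in METRICS}
    n_redraws = 0
    for b in range(B):
        rng = np.random.default_rng([seed, b])  # per-iteration derived stream
        scores = np.empty(n)
        preds = np.empty(n, dtype=int)
        for i in range(n):
            rest = np.delete(np.arange(n), i)
            if identity_resample:
                train = rest
            else:
                while True:
                    train = rest[rng.integers(0, n - 1, size=n - 1)]
                    if len(np.unique(y[train])) == 2:
                        break
                    n_redraws += 1
            model = model_zoo.fit(spec, X[train], y[train])
            s, lab = model_zoo.predict(model, X[i : i + 1])
            scores[i], preds[i] = s[0], lab[0]
        metrics = compute_metrics(PredictionSet(y, preds, scores, iteration=b, seed=seed))
        for m in METRICS:
            values[m][b] = metrics[m]
    if n_redraws:
        warnings.warn(f"{n_redraws} single-class bootstrap resamples were redrawn")
    return {m: MetricDistribution.from_values(m, values[m]) for m in METRICS}


def format_metric(dist: MetricDistribution) -> str:
    return f"{dist.mean:.2f} [{dist.lo:.2f}–{dist.hi:.2f}]"


def run_study(
    run_config,
    feature_table=None,
    cohort_table=None,
    explain: bool = False,
) -> dict:
    """Execute one configured pipeline end to end and return a report.

    Feature-set assembly -> optional wrapper selection (run once on the full
    dataset) -> model evaluation -> Table-style formatted metric row, plus
    selection and (optionally) attribution artifacts.
    """
    from . import cohort_synth, io_config
    from .vlpso_select import SwarmConfig, vlpso_run

    if cohort_table is None:
        feature_table, cohort_table = cohort_synth.generate_cohort(
            cohort_synth.SynthConfig(seed=run_config.seed)
        )
    X, y, names = io_config.assemble_design(
        feature_table, cohort_table, run_config.feature_set
    )

    report: dict = {
        "feature_set": run_config.feature_set,
        "model": run_config.model,
        "evaluation": run_config.evaluation,
        "seed": run_config.seed,
        "config_hash": run_config.config_hash(),
        "n_subjects": int(len(y)),
        "n_features_input": int(X.shape[1]),
    }

    if run_config.model == "vlpso_knn":
        swarm = SwarmConfig(**{**(run_config.swarm or {}), "seed": run_config.seed})
        selection = vlpso_run(X, y, swarm, feature_names=names)
        sel = np.array(selection.selected_indices, dtype=int)
        X = X[:, sel]
        names = list(selection.selected_names)
        spec = ModelSpec(
            family="knn", hyperparameters={"k": swarm.knn_k}, seed=run_config.seed
        )
        report["selection"] = {
            "selected_names": list(selection.selected_names),
            "selected_indices": [int(j) for j in selection.selected_indices],
            "best_fitness": selection.best_fitness,
            "n_evaluations": selection.n_evaluations,
        }
    else:
        spec = ModelSpec(
            family=run_config.model,
            hyperparameters=dict(run_config.model_params),
            seed=run_config.seed,
        )

    if run_config.evaluation == "loocv":
        pred = loocv(spec, X, y, seed=run_config.seed)
        metrics = compute_metrics(pred)
        report["metrics"] = {m: {"mean": v} for m, v in metrics.items()}
        report["row"] = {m: f"{v:.2f}" for m, v in metrics.items()}
    else:
        dists = bootstrap_loocv(spec, X, y, B=run_config.n_bootstrap, seed=run_config.seed)
        report["metrics"] = {
            m: {"mean": d.mean, "lo": d.lo, "hi": d.hi, "B": len(d.values)}
            for m, d in dists.items()
        }
        report["row"] = {m: format_metric(d) for m, d in dists.items()}

    if explain and X.shape[1] <= 20:
        from .explain import explain_cohort

        explanations, importance = explain_cohort(spec, X, y, list(range(X.shape[1])),
                                                  seed=run_config.seed, names=names)
        report["importance"] = importance.to_dict(orient="records")
    return report
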