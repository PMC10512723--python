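"""Classifier families behind a single fit/predict contract.

Elastic-net logistic regression, random forest, and PCA-preceded elastic
net / logistic / SVM / KNN variants. Every model standardizes columns with
training statistics only; PCA loadings are likewise frozen from training
data, so no test-set information leaks into preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._knn import KNNVote

__all__ = ["ModelSpec", "FittedModel", "fit", "predict", "FAMILIES"]

FAMILIES = (
    "elastic_net",
    "random_forest",
    "pca_elastic_net",
    "pca_logistic",
    "pca_svm",
    "pca_knn",
    "knn",
)


@dataclass(frozen=True)
class ModelSpec:
    family: str = "knn"
    pca_components: int = 9
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")

    @property
    def uses_pca(self) -> bool:
        return self.family.startswith("pca_")


@dataclass
class FittedModel:
    spec: ModelSpec
    column_names: tuple[str, ...] | None
    keep: np.ndarray          # mask of non-degenerate training columns
    impute_means: np.ndarray  # training-fold means used for missing cells
    mean: np.ndarray
    sd: np.ndarray
    pca: PCA | None
    clf: object
    calibrator: LogisticRegression | None = None
    prevalence: float = 0.5

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.keep):
            raise ValueError(
                f"schema mismatch: model fitted on {len(self.keep)} columns, "
                f"got {X.shape[1]}"
            )
        if np.isnan(X).any():
            X = np.where(np.isnan(X), self.impute_means, X)
        Z = (X[:, self.keep] - self.mean) / self.sd
        return self.pca.transform(Z) if self.pca is not None else Z


def _choose_en_penalty(
    Z: np.ndarray, y: np.ndarray, l1_ratio: float, seed: int
) -> float:
    """Inner seeded 5-fold CV over a 20-point logarithmic grid of C."""
    grid = np.logspace(-3, 2, 20)
    minority = int(min((y == 1).sum(), (y == 0).sum()))
    folds = max(2, min(5, minority))
    if minority < 2:
        return 1.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_c, best_acc = grid[0], -1.0
    for c in grid:
        accs = []
        for train, test in skf.split(Z, y):
            clf = LogisticRegression(
                solver="saga", l1_ratio=l1_ratio, C=c, max_iter=5000,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Z[train], y[train])
            accs.append(float((clf.predict(Z[test]) == y[test]).mean()))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:  # ties keep the stronger penalty (smaller C)
            best_acc, best_c = acc, c
    return float(best_c)


def fit(spec: ModelSpec, X_train: np.ndarray, y_train: np.ndarray,
        column_names: list[str] | None = None) -> FittedModel:
    """Fit one model family on training data only."""
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = np.asarray(y_train, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y_train")
    hp = spec.hyperparameters

    # Missing cells are mean-imputed with training-fold statistics only.
    impute_means = np.nanmean(X, axis=0)
    impute_means = np.where(np.isnan(impute_means), 0.0, impute_means)
    if np.isnan(X).any():
        X = np.where(np.isnan(X), impute_means, X)

    sd_all = X.std(axis=0)
    keep = sd_all > 0
    if not keep.all():
        dropped = np.flatnonzero(~keep)
        names = [column_names[j] for j in dropped] if column_names else list(dropped)
        warnings.warn(f"dropping zero-variance columns: {names}")
    if not keep.any():
        raise ValueError("all columns are degenerate")
    mean = X[:, keep].mean(axis=0)
    sd = X[:, keep].std(axis=0)
    Z = (X[:, keep] - mean) / sd

    pca = None
    if spec.uses_pca:
        n_comp = min(spec.pca_components, Z.shape[0], Z.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=spec.seed)
        Z = pca.fit_transform(Z)

    family = spec.family
    calibrator = None
    if family in ("elastic_net", "pca_elastic_net"):
        l1_ratio = float(hp.get("l1_ratio", 0.5))
        c = float(hp["C"]) if "C" in hp else _choose_en_penalty(Z, y, l1_ratio, spec.seed)
        clf = LogisticRegression(
            solver="saga", l1_ratio=l1_ratio, C=c, max_iter=5000,
            random_state=spec.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Z, y)
    elif family == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 500)),
            max_depth=hp.get("max_depth"),
            max_features=hp.get("max_features", "sqrt"),
            random_state=spec.seed,
        )
        clf.fit(Z, y)
    elif family == "pca_logistic":
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        clf.fit(Z, y)
    elif family == "pca_svm":
        clf = SVC(
            kernel=hp.get("kernel", "rbf"),
            gamma=hp.get("gamma", 1.0 / Z.shape[1]),
            C=float(hp.get("C", 1.0)),
            random_state=spec.seed,
        )
        clf.fit(Z, y)
        dec = clf.decision_function(Z).reshape(-1, 1)
        calibrator = LogisticRegression(max_iter=1000)
        calibrator.fit(dec, y)
    elif family in ("knn", "pca_knn"):
        clf = KNNVote(k=int(hp.get("k", 5))).fit(Z, y)
    else:  # pragma: no cover
        raise AssertionError(family)

    return FittedModel(
        spec=spec,
        column_names=tuple(column_names) if column_names else None,
        keep=keep, impute_means=impute_means, mean=mean, sd=sd, pca=pca, clf=clf,
        calibrator=calibrator, prevalence=float(y.mean()),
    )


def predict(model: FittedModel, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class scores in [0, 1] and hard labels (score >= 0.5)."""
    Z = model.transform(X_test)
    family = model.spec.family
    if family in ("knn", "pca_knn"):
        scores = model.clf.scores(Z)
    elif family == "pca_svm":
        dec = model.clf.decision_function(Z).reshape(-1, 1)
        scores = model.calibrator.predict_proba(dec)[:, 1]
    else:
        pos_col = int(np.flatnonzero(model.clf.classes_ == 1)[0])
        scores = model.clf.predict_proba(Z)[:, pos_col]
    scores = np.clip(scores, 0.0, 1.0)
    return scores, (scores >= 0.5).astype(int)


def score_function(model: FittedModel):
    """Positive-class score callable over raw-feature rows."""
    return lambda X: predict(model, X)[0]
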