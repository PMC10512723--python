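"""Table readers/writers, run configuration, and design-matrix assembly."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_synth import CohortTable, FeatureTable
from .schema import DEMOGRAPHIC_VARIABLES, NEUROPSYCH_VARIABLES, acoustic_schema

__all__ = [
    "RunConfig",
    "read_feature_csv",
    "write_feature_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "assemble_design",
    "FEATURE_SETS",
    "MODELS",
]

log = logging.getLogger("amyvox")

FEATURE_SETS = ("neuropsych_demographic", "acoustic", "acoustic_demographic")
MODELS = (
    "elastic_net",
    "random_forest",
    "pca_elastic_net",
    "pca_logistic",
    "pca_svm",
    "pca_knn",
    "knn",
    "vlpso_knn",
)
EVALUATIONS = ("loocv", "bootstrap_loocv")


@dataclass(frozen=True)
class RunConfig:
    """One end-to-end pipeline run: feature set, model, evaluation scheme."""

    feature_set: str = "acoustic"
    model: str = "vlpso_knn"
    evaluation: str = "bootstrap_loocv"
    n_bootstrap: int = 5000
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    swarm: dict | None = None
    model_params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.evaluation not in EVALUATIONS:
            raise ValueError(f"evaluation must be one of {EVALUATIONS}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        # Wrapper selection is only offered for acoustic-bearing feature sets.
        if self.model == "vlpso_knn" and self.feature_set == "neuropsych_demographic":
            raise ValueError(
                "vlpso_knn is not offered for the neuropsych_demographic feature set"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text(encoding="utf-8").splitlines()[0]
    return ";" if first.count(";") > first.count(",") else ","


def read_feature_csv(path: str | Path, strict_schema: bool = False) -> FeatureTable:
    """Read a subjects x features table from CSV.

    Accepts both a plain comma-separated file and the semicolon-separated
    functional-summary dialect (leading ``name`` column, optional
    ``frameTime``). The first column is taken as the subject identifier.
    When all 88 canonical acoustic names are present, columns are reordered
    to the canonical schema; ``strict_schema`` additionally requires exactly
    that schema.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if df.columns[0].lower() in ("name", "file"):
        df = df.rename(columns={df.columns[0]: "subject_id"})
    id_col = df.columns[0]
    df = df.drop(columns=[c for c in df.columns[1:] if c.lower() == "frametime"])
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate subject ids: {dupes}")

    value_cols = list(df.columns[1:])
    values = df[value_cols]
    bad = values.apply(pd.to_numeric, errors="coerce")
    if bad.isna().values.any() and not values.isna().values.any():
        r, c = np.argwhere(bad.isna().values)[0]
        raise ValueError(
            f"non-numeric cell at row {int(r)}, column {value_cols[int(c)]!r}"
        )
    schema = acoustic_schema()
    if strict_schema:
        missing = [name for name in schema if name not in value_cols]
        if missing:
            raise ValueError(f"missing acoustic columns: {missing}")
        unknown = [name for name in value_cols if name not in schema]
        if unknown:
            raise ValueError(f"unknown acoustic columns: {unknown}")
    if set(schema).issubset(value_cols):
        ordered = list(schema) + [c for c in value_cols if c not in set(schema)]
        bad = bad[ordered]
        value_cols = ordered
    return FeatureTable(tuple(ids), tuple(value_cols), bad.to_numpy(dtype=float))


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep=_sniff_delimiter(Path(path)))
    df["subject_id"] = df["subject_id"].astype(str)
    return CohortTable(df)


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def assemble_design(
    feature_table: FeatureTable | None,
    cohort_table: CohortTable,
    feature_set: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build the (matrix, labels, column names) triple for one feature set.

    Column conventions: sex encoded 0/1 with female=1; labels positive=1.
    Feature sets: ``neuropsych_demographic`` = 13 scores + age/sex/education;
    ``acoustic`` = the acoustic columns; ``acoustic_demographic`` = both.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    cf = cohort_table.frame
    labels = cohort_table.labels

    demo = np.column_stack(
        [
            cf["age"].to_numpy(float),
            (cf["sex"] == "female").to_numpy(dtype=float),
            cf["education"].to_numpy(float),
        ]
    )

    if feature_set == "neuropsych_demographic":
        neuro = cf[list(NEUROPSYCH_VARIABLES)].to_numpy(float)
        X = np.hstack([neuro, demo])
        names = list(NEUROPSYCH_VARIABLES) + list(DEMOGRAPHIC_VARIABLES)
        return X, labels, names

    if feature_table is None:
        raise ValueError(f"feature_set {feature_set!r} requires an acoustic table")
    cohort_ids = list(cohort_table.subject_ids)
    feat_ids = list(feature_table.subject_ids)
    orphans = sorted(set(cohort_ids) ^ set(feat_ids))
    if orphans:
        raise ValueError(f"subject ids do not match one-to-one; unmatched: {orphans}")
    order = [feat_ids.index(s) for s in cohort_ids]
    acoustic = feature_table.values[order]

    if feature_set == "acoustic":
        return acoustic, labels, list(feature_table.feature_names)
    # Combined design carries sex as two complementary indicators, matching
    # the published 92-variable count (88 acoustic + age + education + 2).
    female = (cf["sex"] == "female").to_numpy(dtype=float)
    demo_wide = np.column_stack(
        [cf["age"].to_numpy(float), female, 1.0 - female, cf["education"].to_numpy(float)]
    )
    X = np.hstack([acoustic, demo_wide])
    names = list(feature_table.feature_names) + ["age", "sex_female", "sex_male", "education"]
    return X, labels, names


def impute_train_means(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing values using training-fold statistics only."""
    X_train = np.array(X_train, dtype=float)
    X_test = np.array(X_test, dtype=float)
    means = np.nanmean(X_train, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    for X in (X_train, X_test):
        idx = np.argwhere(np.isnan(X))
        if idx.size:
            X[idx[:, 0], idx[:, 1]] = means[idx[:, 1]]
    return X_train, X_test
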