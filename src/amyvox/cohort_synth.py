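"""Synthetic case-control cohort generator.

Emulates the statistical structure of a 52-subject memory-clinic cohort:
group-specific demographics and neuropsychological scores, CSF Abeta42
values consistent with the 796 pg/mL dichotomization cutoff, and an
equicorrelated 88-column acoustic block with a small planted set of
group-discriminative features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    ABETA_CUTOFF,
    KEY_ACOUSTIC_FEATURES,
    NEUROPSYCH_VARIABLES,
    acoustic_schema,
)

__all__ = [
    "SynthConfig",
    "GroupParams",
    "FeatureTable",
    "CohortTable",
    "generate_cohort",
    "dichotomize_amyloid",
]


class ConfigError(ValueError):
    """Raised when a configuration field violates its contract."""


@dataclass(frozen=True)
class GroupParams:
    """Per-group marginals for demographics and neuropsychological scores.

    ``neuropsych`` maps score name -> (mean, sd); scores are truncated at 0.
    """

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    female_prop: float
    neuropsych: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_prop <= 1.0:
            raise ConfigError("female_prop must lie in [0, 1]")
        for name, (_, sd) in self.neuropsych.items():
            if sd < 0:
                raise ConfigError(f"neuropsych sd for {name!r} must be >= 0")


# Group summaries (mean, sd) for each neuropsychological score,
# amyloid-positive and -negative groups respectively.
_NEUROPSYCH_POSITIVE = {
    "wais_digit_forward": (6.4, 0.9),
    "wais_digit_backward": (3.7, 1.1),
    "wms_delayed_recall": (1.2, 1.7),
    "wms_recognition": (18.4, 3.6),
    "objects_15": (9.4, 3.1),
    "poppelreuter_figures": (9.1, 1.1),
    "skt_time": (40.7, 16.2),
    "phonetic_fluency": (9.4, 5.0),
    "semantic_fluency": (11.6, 4.8),
    "wais_similarities": (7.8, 2.8),
    "bnt_15": (12.3, 2.5),
    "verbal_comprehension": (5.7, 0.5),
    "luria_clock": (3.0, 1.1),
}
_NEUROPSYCH_NEGATIVE = {
    "wais_digit_forward": (7.0, 1.9),
    "wais_digit_backward": (4.4, 1.6),
    "wms_delayed_recall": (3.2, 2.2),
    "wms_recognition": (21.0, 2.4),
    "objects_15": (11.3, 2.4),
    "poppelreuter_figures": (9.5, 0.8),
    "skt_time": (32.0, 12.2),
    "phonetic_fluency": (11.9, 3.8),
    "semantic_fluency": (14.4, 4.8),
    "wais_similarities": (10.8, 3.0),
    "bnt_15": (14.1, 1.2),
    "verbal_comprehension": (5.8, 0.3),
    "luria_clock": (3.2, 1.1),
}


def _default_group_params() -> dict[str, GroupParams]:
    return {
        "positive": GroupParams(
            age_mean=76.8, age_sd=4.5,
            education_mean=7.4, education_sd=4.3,
            female_prop=0.633,
            neuropsych=dict(_NEUROPSYCH_POSITIVE),
        ),
        "negative": GroupParams(
            age_mean=69.4, age_sd=10.6,
            education_mean=10.6, education_sd=4.5,
            female_prop=0.682,
            neuropsych=dict(_NEUROPSYCH_NEGATIVE),
        ),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of the cohort generator."""

    n_subjects: int = 52
    n_positive: int = 30
    n_acoustic: int = 88
    informative_features: tuple[str, ...] = KEY_ACOUSTIC_FEATURES
    effect_size: float = 0.8
    correlation: float = 0.3
    group_params: dict[str, GroupParams] = field(default_factory=_default_group_params)
    # (mean, sd) of Abeta42 per group; positive truncated below the cutoff,
    # negative truncated at/above it, so labels are consistent by construction.
    abeta_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"positive": (600.0, 100.0), "negative": (1100.0, 250.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not 0 <= self.n_positive <= self.n_subjects:
            raise ConfigError("n_positive must satisfy 0 <= n_positive <= n_subjects")
        if self.n_acoustic < 1:
            raise ConfigError("n_acoustic must be >= 1")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if not 0.0 <= self.correlation < 1.0:
            raise ConfigError("correlation must lie in [0, 1)")
        schema = self.feature_names()
        unknown = [f for f in self.informative_features if f not in schema]
        if unknown:
            raise ConfigError(f"informative_features not in acoustic schema: {unknown}")
        for grp in ("positive", "negative"):
            if grp not in self.group_params:
                raise ConfigError(f"group_params missing group {grp!r}")
            if grp not in self.abeta_params:
                raise ConfigError(f"abeta_params missing group {grp!r}")
            if self.abeta_params[grp][1] <= 0:
                raise ConfigError(f"abeta_params sd for {grp!r} must be > 0")

    def feature_names(self) -> tuple[str, ...]:
        """Acoustic column names: the canonical schema, truncated or padded."""
        schema = acoustic_schema()
        if self.n_acoustic <= len(schema):
            return schema[: self.n_acoustic]
        extra = tuple(f"synthetic_{i:03d}" for i in range(self.n_acoustic - len(schema)))
        return schema + extra


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x acoustic-features numeric matrix with named columns."""

    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/feature names")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "subject_id", list(self.subject_ids))
        return df


@dataclass(frozen=True)
class CohortTable:
    """Per-subject demographics, neuropsychology, Abeta42 and amyloid label."""

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "age", "sex", "education", "amyloid_status")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.frame["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in cohort table")
        if "abeta42" in self.frame.columns:
            expected = self.frame["abeta42"].map(dichotomize_amyloid)
            if not (expected == self.frame["amyloid_status"]).all():
                raise ValueError("amyloid_status inconsistent with abeta42 cutoff")

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["subject_id"])

    @property
    def labels(self) -> np.ndarray:
        """Binary labels, positive amyloid status = 1."""
        return (self.frame["amyloid_status"] == "positive").to_numpy(dtype=int)


def dichotomize_amyloid(abeta42: float) -> str:
    """Dichotomize a CSF Abeta42 concentration (pg/mL) at the 796 cutoff.

    Returns ``"positive"`` iff the value is strictly below the cutoff.
    """
    if abeta42 is None or (isinstance(abeta42, float) and math.isnan(abeta42)):
        raise ValueError("abeta42 is missing")
    if abeta42 <= 0:
        raise ValueError(f"abeta42 must be positive, got {abeta42}")
    return "positive" if abeta42 < ABETA_CUTOFF else "negative"


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    low: float = -np.inf,
    high: float = np.inf,
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SynthConfig) -> tuple[FeatureTable, CohortTable]:
    """Draw one synthetic cohort.

    Exactly ``config.n_positive`` subjects are labeled positive. Informative
    acoustic columns receive a mean shift of ``effect_size`` (the columns have
    unit variance, so the shift equals effect_size pooled SDs in expectation);
    all other acoustic columns are identically distributed in both groups.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_acoustic
    feature_names = config.feature_names()

    status = np.zeros(n, dtype=int)
    status[: config.n_positive] = 1
    status = rng.permutation(status)

    # Equicorrelated standard-normal block via a shared factor:
    # x = sqrt(rho) * g + sqrt(1 - rho) * e  has corr(x_i, x_j) = rho.
    rho = config.correlation
    shared = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, p))
    acoustic = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise
    informative_idx = [feature_names.index(f) for f in config.informative_features]
    if informative_idx:
        acoustic[np.ix_(status == 1, informative_idx)] += config.effect_size

    ids = tuple(f"S{i + 1:03d}" for i in range(n))
    features = FeatureTable(ids, feature_names, acoustic)

    rows: dict[str, np.ndarray | list] = {"subject_id": list(ids)}
    age = np.empty(n)
    education = np.empty(n)
    sex = np.empty(n, dtype=object)
    abeta = np.empty(n)
    neuro = {name: np.empty(n) for name in NEUROPSYCH_VARIABLES}

    for grp, mask in (("positive", status == 1), ("negative", status == 0)):
        k = int(mask.sum())
        if k == 0:
            continue
        gp = config.group_params[grp]
        age[mask] = _truncated_normal(rng, gp.age_mean, gp.age_sd, k, low=18.0)
        education[mask] = _truncated_normal(rng, gp.education_mean, gp.education_sd, k, low=0.0)
        sex[mask] = np.where(rng.random(k) < gp.female_prop, "female", "male")
        mean_ab, sd_ab = config.abeta_params[grp]
        if grp == "positive":
            abeta[mask] = _truncated_normal(rng, mean_ab, sd_ab, k, low=1.0, high=ABETA_CUTOFF)
        else:
            abeta[mask] = _truncated_normal(rng, mean_ab, sd_ab, k, low=ABETA_CUTOFF)
        for name in NEUROPSYCH_VARIABLES:
            mu, sd = gp.neuropsych[name]
            neuro[name][mask] = _truncated_normal(rng, mu, sd, k, low=0.0)

    rows["age"] = age
    rows["sex"] = sex
    rows["education"] = education
    rows.update(neuro)
    rows["abeta42"] = abeta
    rows["amyloid_status"] = np.where(status == 1, "positive", "negative")
    cohort = CohortTable(pd.DataFrame(rows))
    return features, cohort


def null_config(config: SynthConfig) -> SynthConfig:
    """Return a copy of ``config`` with all group effects removed.

    Acoustic effect size is set to zero and demographic/neuropsychological
    marginals are pooled (positive-group parameters used for both groups),
    so the label carries no information.
    """
    pooled = config.group_params["positive"]
    return replace(
        config,
        effect_size=0.0,
        group_params={"positive": pooled, "negative": pooled},
    )
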