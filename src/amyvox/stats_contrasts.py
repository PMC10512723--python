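"""Bivariate and covariate-adjusted contrasts between amyloid groups.

Pooled-variance two-sample t statistics (reported as absolute values),
continuity-corrected chi-square for 2x2 tables, and covariate-adjusted
logistic models. No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_synth import CohortTable, FeatureTable
from .schema import NEUROPSYCH_VARIABLES

__all__ = [
    "ContrastResult",
    "pooled_t",
    "pooled_t_vectors",
    "chi2_corrected",
    "adjusted_logistic",
    "contrast_table",
]


@dataclass(frozen=True)
class ContrastResult:
    variable: str
    summary_pos: str
    summary_neg: str
    statistic: float
    kind: str  # "pooled_t" | "chi2_corrected"
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test from group summaries; |t| is returned.

    Pooled-variance by default; Welch-Satterthwaite when ``welch`` is set.
    Returns (|t|, df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    diff = mean1 - mean2
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if se > 0 else n1 + n2 - 2
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    if se == 0:
        if diff == 0:
            return 0.0, float(df), 1.0
        warnings.warn("zero pooled variance with unequal means; t is infinite")
        return float("inf"), float(df), 0.0
    t = abs(diff) / se
    p = 2.0 * stats.t.sf(t, df)
    return float(t), float(df), float(p)


def pooled_t_vectors(
    x1: np.ndarray, x2: np.ndarray, welch: bool = False
) -> tuple[float, float, float]:
    """Raw-vector overload of :func:`pooled_t` (summaries computed first)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return pooled_t(
        float(np.mean(x1)), float(np.std(x1, ddof=1)), len(x1),
        float(np.mean(x2)), float(np.std(x2, ddof=1)), len(x2),
        welch=welch,
    )


def chi2_corrected(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for the 2x2 table [[a,b],[c,d]].

    chi2 = n (|ad - bc| - n/2)^2 / (r1 r2 c1 c2), floored at 0 when the
    absolute cross-product difference does not exceed n/2.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("all table margins must be > 0")
    cross = abs(a * d - b * c)
    if cross <= n / 2:
        chi2 = 0.0
        corrected = 0.0
    else:
        corrected = cross - n / 2
        chi2 = n * corrected**2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass(frozen=True)
class LogisticResult:
    coefficient: float
    odds_ratio: float
    p_value: float
    separated: bool


def _irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Maximum-likelihood logistic fit by iteratively reweighted least squares."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError as exc:
            raise ValueError("design matrix is rank deficient") from exc
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov


def adjusted_logistic(
    labels: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None = None,
) -> LogisticResult:
    """Logistic model of binary labels on a predictor, adjusting for covariates.

    Returns the predictor's coefficient, odds ratio exp(beta), and Wald
    two-sided p-value. Perfect separation (standardized coefficient diverging
    beyond 15) is flagged rather than reported as a finite estimate.
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must be binary with both classes present")
    if np.std(x) == 0:
        raise ValueError("predictor is constant (rank deficient)")
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(x):
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, covm = _irls_logistic(X, y)
    coef = float(beta[1])
    se = float(np.sqrt(covm[1, 1]))
    std_coef = coef * float(np.std(x))
    separated = abs(std_coef) > 15.0
    if separated:
        warnings.warn("perfect separation suspected; coefficient diverges")
        return LogisticResult(coef, float(np.exp(np.clip(coef, -700, 700))), float("nan"), True)
    z = coef / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return LogisticResult(coef, float(np.exp(coef)), p, False)


def contrast_table(
    feature_table: FeatureTable | None, cohort_table: CohortTable
) -> list[ContrastResult]:
    """Per-variable group contrasts for a labeled cohort.

    Numeric variables (demographics, neuropsychology, acoustics) use the
    pooled-variance t; sex uses the corrected chi-square.
    """
    cf = cohort_table.frame
    pos = cf["amyloid_status"] == "positive"
    results: list[ContrastResult] = []

    def add_numeric(name: str, values: np.ndarray) -> None:
        x1, x2 = values[pos.to_numpy()], values[~pos.to_numpy()]
        t, df, p = pooled_t_vectors(x1, x2)
        results.append(
            ContrastResult(
                name,
                f"{np.mean(x1):.1f} ({np.std(x1, ddof=1):.1f})",
                f"{np.mean(x2):.1f} ({np.std(x2, ddof=1):.1f})",
                round(t, 2), "pooled_t", df, p,
            )
        )

    add_numeric("age", cf["age"].to_numpy(float))

    a = int(((cf["sex"] == "female") & pos).sum())
    b = int(((cf["sex"] != "female") & pos).sum())
    c = int(((cf["sex"] == "female") & ~pos).sum())
    d = int(((cf["sex"] != "female") & ~pos).sum())
    chi2, p = chi2_corrected(a, b, c, d)
    results.append(
        ContrastResult(
            "sex",
            f"{100 * a / (a + b):.1f}", f"{100 * c / (c + d):.1f}",
            round(chi2, 2), "chi2_corrected", 1.0, p,
        )
    )

    add_numeric("education", cf["education"].to_numpy(float))
    for name in NEUROPSYCH_VARIABLES:
        if name in cf.columns:
            add_numeric(name, cf[name].to_numpy(float))
    if feature_table is not None:
        order = [list(feature_table.subject_ids).index(s) for s in cohort_table.subject_ids]
        values = feature_table.values[order]
        for j, name in enumerate(feature_table.feature_names):
            add_numeric(name, values[:, j])
    return results


def contrast_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "positive_group": [r.summary_pos for r in results],
            "negative_group": [r.summary_neg for r in results],
            "statistic": [r.statistic for r in results],
            "kind": [r.kind for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
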