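"""Standardized-beta association models for participant-level HDI_M.

Ordinary least squares with the outcome and the main predictor z-scored on
the complete-case analysis sample, so the predictor coefficient is a
standardized beta: SD of outcome per SD of predictor. Covariates enter on
their raw scales (sex coded F=0, M=1). Three covariate sets are fitted per
outcome: univariate; Model 1 = age + sex + BMI, with height replacing BMI
for weight-standardized outcomes (leg power, VO2 peak); Model 2 = age +
sex + thigh muscle volume index + total abdominal adipose tissue index.
A sex x predictor interaction term added to Model 1 tests whether
associations differ between women and men (Wald two-sided p). Significance
is two-sided at 0.05 with no multiplicity adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "WEIGHT_STANDARDIZED_OUTCOMES",
    "standardized_ols",
    "fit_outcome_models",
    "sex_interaction_test",
]

MODEL1_COVARIATES = ("age", "sex", "bmi")
MODEL1_COVARIATES_WEIGHT_STD = ("age", "sex", "height")
MODEL2_COVARIATES = ("age", "sex", "muscle_volume_index_z", "adipose_index")

#: outcomes already standardized for body weight: Model 1 swaps BMI for height
WEIGHT_STANDARDIZED_OUTCOMES = ("leg_power", "vo2peak")


class SchemaError(KeyError):
    """A required column is missing from the participant table."""


@dataclass
class RegressionResult:
    outcome: str
    model_id: str
    beta_std: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates: tuple[str, ...]


def _design(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    X = df.loc[:, list(cols)].copy()
    if "sex" in X:
        X["sex"] = (X["sex"].astype(str) == "M").astype(float)
    return X.astype(float)


def standardized_ols(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = (),
    model_id: str = "custom",
) -> RegressionResult:
    """OLS with z-scored outcome and predictor; normal-theory 95% CI.

    Complete cases only (listwise deletion, logged); standardization uses
    the analysis sample's mean and (n-1)-denominator SD. Covariates are
    untransformed.
    """
    cols = [outcome, predictor, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    d = data.loc[:, cols].dropna()
    n_drop = len(data) - len(d)
    if n_drop:
        logger.info("%s/%s: %d incomplete cases dropped", outcome, model_id, n_drop)
    n = len(d)
    if n <= len(cols) + 1:
        raise ValueError(f"too few complete cases (n={n}) for {len(cols)} parameters")
    y = d[outcome].astype(float)
    x = d[predictor].astype(float)
    if y.std(ddof=1) == 0 or x.std(ddof=1) == 0:
        raise ValueError("constant outcome or predictor")
    yz = (y - y.mean()) / y.std(ddof=1)
    xz = (x - x.mean()) / x.std(ddof=1)
    X = pd.DataFrame({predictor: xz})
    if covariates:
        X = pd.concat([X, _design(d, covariates)], axis=1)
    X = sm.add_constant(X)
    fit = sm.OLS(yz.to_numpy(), X.to_numpy()).fit()
    i = list(X.columns).index(predictor)
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        outcome,
        model_id,
        float(fit.params[i]),
        float(ci[i, 0]),
        float(ci[i, 1]),
        float(fit.pvalues[i]),
        n,
        tuple(covariates),
    )


def model1_covariates(outcome: str) -> tuple[str, ...]:
    if outcome in WEIGHT_STANDARDIZED_OUTCOMES:
        return MODEL1_COVARIATES_WEIGHT_STD
    return MODEL1_COVARIATES


def fit_outcome_models(
    participants: pd.DataFrame,
    outcomes: Sequence[str],
    predictor: str = "hdi",
) -> list[RegressionResult]:
    """Univariate, Model 1, and Model 2 fits for each outcome."""
    results = []
    for outcome in outcomes:
        for model_id, covs in (
            ("univariate", ()),
            ("model1", model1_covariates(outcome)),
            ("model2", MODEL2_COVARIATES),
        ):
            results.append(
                standardized_ols(participants, outcome, predictor, covs, model_id)
            )
    return results


def sex_interaction_test(
    data: pd.DataFrame,
    outcome: str,
    predictor: str = "hdi",
    covariates: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Wald test of a sex x predictor interaction added to Model 1.

    Returns (interaction coefficient, two-sided p). Requires both sexes.
    """
    covs = tuple(covariates) if covariates is not None else model1_covariates(outcome)
    if "sex" not in covs:
        covs = ("sex", *covs)
    cols = [outcome, predictor, *covs]
    d = data.loc[:, cols].dropna()
    sexes = set(d["sex"].astype(str))
    if len(sexes) < 2:
        raise ValueError("sex interaction requires both sexes in the sample")
    y = d[outcome].astype(float)
    x = d[predictor].astype(float)
    yz = (y - y.mean()) / y.std(ddof=1)
    xz = (x - x.mean()) / x.std(ddof=1)
    X = pd.DataFrame({predictor: xz})
    X = pd.concat([X, _design(d, covs)], axis=1)
    X["sex_x_" + predictor] = X["sex"] * xz
    X = sm.add_constant(X)
    fit = sm.OLS(yz.to_numpy(), X.to_numpy()).fit()
    i = list(X.columns).index("sex_x_" + predictor)
    return float(fit.params[i]), float(fit.pvalues[i])


def results_table(results: list[RegressionResult]) -> pd.DataFrame:
    """Long-format table of regression results (one row per outcome/model)."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "model": r.model_id,
                "beta_std": r.beta_std,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n": r.n,
                "covariates": "+".join(r.covariates),
            }
            for r in results
        ]
    )
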