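"""Staged multivariable logistic models of a log-transformed exposure.

A positively skewed serum biomarker is log-transformed (natural log,
internally) and related to binary outcomes through logistic regression in
ordered stages of covariate adjustment.  Coefficients on the ln scale are
multiplied by ln(2) before exponentiation, giving an odds ratio per
doubling of the biomarker; an OR per SD of the log-exposure is reported
alongside for comparison with MR estimates.  Interaction and stratified
variants follow the same fitting conventions (Wald CIs and p-values, no
multiple-testing correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ObservationalResult",
    "staged_logistic",
    "interaction_model",
    "stratified_run",
]

_LN2 = math.log(2.0)
_Z = 1.959963984540054  # two-sided 95%


@dataclass(frozen=True)
class ObservationalResult:
    model_label: str
    or_per_doubling: float
    ci_per_doubling: tuple[float, float]
    p: float
    or_per_sd: float
    ci_per_sd: tuple[float, float]
    n_used: int


def _fit_logit(y: np.ndarray, X: np.ndarray):
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation, singular Hessian, ...
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (possible separation)")
    if np.any(~np.isfinite(fit.bse)):
        raise RuntimeError("non-finite standard errors (possible separation or collinearity)")
    return fit


def _design(df: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KeyError(f"covariates not in table: {missing}")
    return np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in columns])


def staged_logistic(
    table: pd.DataFrame,
    exposure: str,
    outcome: str,
    stages: Sequence[tuple[str, Sequence[str]]],
) -> list[ObservationalResult]:
    """Fit outcome ~ ln(exposure) + covariates for each adjustment stage.

    ``stages`` is an ordered list of (label, covariate-name list); stage
    covariate lists are taken as given (they need not be nested).  The
    exposure must be strictly positive.
    """
    x_raw = table[exposure].to_numpy(float)
    bad = np.flatnonzero(~(x_raw > 0))
    if bad.size:
        raise ValueError(
            f"exposure {exposure!r} must be strictly positive; "
            f"offending rows (0-based): {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else "")
        )
    y = table[outcome].to_numpy(float)
    ln_x = np.log(x_raw)
    ln_x_std = (ln_x - ln_x.mean()) / ln_x.std()

    results = []
    for label, covs in stages:
        C = _design(table, covs)
        fit = _fit_logit(y, np.column_stack([ln_x, C]))
        b, se = fit.params[0], fit.bse[0]
        fit_sd = _fit_logit(y, np.column_stack([ln_x_std, C]))
        b_sd, se_sd = fit_sd.params[0], fit_sd.bse[0]
        results.append(
            ObservationalResult(
                model_label=label,
                or_per_doubling=math.exp(b * _LN2),
                ci_per_doubling=(
                    math.exp((b - _Z * se) * _LN2),
                    math.exp((b + _Z * se) * _LN2),
                ),
                p=float(fit.pvalues[0]),
                or_per_sd=math.exp(b_sd),
                ci_per_sd=(math.exp(b_sd - _Z * se_sd), math.exp(b_sd + _Z * se_sd)),
                n_used=len(y),
            )
        )
    return results


def interaction_model(
    table: pd.DataFrame,
    exposure: str,
    moderator: str,
    outcome: str,
    covariates: Sequence[str] = (),
    *,
    log_exposure: bool = True,
) -> dict:
    """Logistic fit with an exposure x moderator product term.

    Returns the product-term OR, 95% CI and p (plus the raw coefficient).
    The exposure is ln-transformed by default to match the staged models.
    """
    x = table[exposure].to_numpy(float)
    if log_exposure:
        if np.any(~(x > 0)):
            raise ValueError("exposure must be strictly positive for the log transform")
        x = np.log(x)
    m = table[moderator].to_numpy(float)
    y = table[outcome].to_numpy(float)
    C = _design(table, covariates)
    X = np.column_stack([x * m, x, m, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient interaction design (collinear moderator?)")
    fit = _fit_logit(y, X)
    b, se = float(fit.params[0]), float(fit.bse[0])
    return {
        "coef": b,
        "se": se,
        "or": math.exp(b),
        "ci": (math.exp(b - _Z * se), math.exp(b + _Z * se)),
        "p": float(fit.pvalues[0]),
        "n_used": len(y),
    }


def stratified_run(
    table: pd.DataFrame,
    stratum_variable: str,
    analysis: Callable[[pd.DataFrame], object],
    *,
    outcome: str | None = None,
) -> dict:
    """Repeat an analysis closure within each level of a stratum variable.

    Strata with zero cases or zero controls (when ``outcome`` is given) are
    skipped with a warning.  Returns {stratum level: analysis result}.
    """
    results = {}
    for level, sub in table.groupby(stratum_variable, sort=True):
        if outcome is not None:
            y = sub[outcome]
            if y.nunique() < 2:
                warnings.warn(
                    f"stratum {stratum_variable}={level!r} has no "
                    f"{'cases' if y.max() == 0 else 'controls'}; skipped"
                )
                continue
        results[level] = analysis(sub.reset_index(drop=True))
    return results
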