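"""Multivariable MR on individual-level data.

Two (or more) exposures — typically the primary biomarker plus a mediator
such as BMI — are instrumented jointly: stage 1 regresses each exposure on
the full instrument set plus covariates; stage 2 regresses the outcome on
all predicted exposures (linear 2SLS or logistic, mirroring the
univariable procedures).  Each exposure's coefficient is its direct effect
conditional on the others.

Instrument strength per exposure conditional on the others is the
Sanderson–Windmeijer conditional F: the exposure is regressed on the other
exposures by 2SLS (using the full instrument set), and the residual is
regressed on the instruments; the resulting F-statistic is rescaled by
k_z/(k_z − K + 1) to account for the other exposures absorbing instrument
space (the Sanderson & Windmeijer 2016 degrees-of-freedom adjustment; with
a single exposure this reduces exactly to the ordinary first-stage F).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .estimates import DiagnosticStats, MREstimate, wald_p
from .onesample import (
    _ols_rss,
    _resolve_covariates,
    _resolve_instruments,
    _resolve_trait,
    first_stage_F,
)
from .simulate import IndividualCohort

__all__ = ["MVMRResult", "mvmr_tsls", "conditional_F"]


@dataclass
class MVMRResult:
    direct_effects: dict  # exposure name -> MREstimate
    conditional_F: dict  # exposure name -> float
    sargan: float | None = None
    sargan_df: int | None = None
    sargan_p: float | None = None


def _stack_instruments(cohort, instruments) -> np.ndarray:
    """Accept one block, or a list of blocks (e.g. two GRSs), column-stacked."""
    if isinstance(instruments, (list, tuple)) and instruments and not isinstance(
        instruments[0], str
    ):
        blocks = [_resolve_instruments(cohort, b) for b in instruments]
        return np.column_stack(blocks)
    return _resolve_instruments(cohort, instruments)


def _exposure_matrix(cohort, exposures) -> tuple[np.ndarray, list[str]]:
    names, cols = [], []
    for i, e in enumerate(exposures):
        names.append(e if isinstance(e, str) else f"exposure{i + 1}")
        x = _resolve_trait(cohort, e)
        cols.append((x - x.mean()) / x.std())  # per-SD scale throughout
    return np.column_stack(cols), names


def mvmr_tsls(
    cohort: IndividualCohort,
    instruments,
    exposures: Sequence = ("exposure", "mediator"),
    outcome="oa",
    covariates: Sequence[str] | np.ndarray | None = ("sex",),
    *,
    stage2: str = "linear",
) -> MVMRResult:
    """Joint two-stage estimation of each exposure's direct effect.

    ``stage2="linear"`` gives 2SLS coefficients with conventional IV SEs
    (risk differences for a binary outcome); ``stage2="logistic"`` fits
    stage 2 by logistic regression on the predicted exposures with naive
    SEs, giving log-odds per SD.
    """
    Z = _stack_instruments(cohort, instruments)
    X, names = _exposure_matrix(cohort, exposures)
    y = _resolve_trait(cohort, outcome)
    C = _resolve_covariates(cohort, covariates)
    n = len(y)
    K = X.shape[1]
    if Z.shape[1] < K:
        raise ValueError(
            f"under-identified: {Z.shape[1]} instruments for {K} exposures"
        )
    W = np.column_stack([np.ones(n)] + ([C] if C is not None else []))
    ZW = np.column_stack([Z, W])
    pi, _, rank, _ = np.linalg.lstsq(ZW, X, rcond=None)
    if rank < ZW.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient first stage")
    Xhat = ZW @ pi
    corr = np.corrcoef(Xhat, rowvar=False)
    if K > 1 and np.max(np.abs(corr[np.triu_indices(K, 1)])) > 0.999:
        cond = np.linalg.cond(np.column_stack([Xhat, W]))
        raise ValueError(
            f"predicted exposures are collinear (condition number {cond:.2e})"
        )

    cF = conditional_F(cohort, instruments, exposures, covariates)
    result = MVMRResult(direct_effects={}, conditional_F=cF)

    if stage2 == "linear":
        Xfull = np.column_stack([X, W])
        Xhfull = np.column_stack([Xhat, W])
        coef, _, _, _ = np.linalg.lstsq(Xhfull, y, rcond=None)
        resid = y - Xfull @ coef
        dof = n - Xfull.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(Xhfull.T @ Xhfull)
        binary = set(np.unique(y)) <= {0.0, 1.0}
        scale = "risk_difference_per_sd" if binary else "linear_per_sd"
        for i, name in enumerate(names):
            est, se = float(coef[i]), math.sqrt(cov[i, i])
            result.direct_effects[name] = MREstimate(
                method="MVMR 2SLS",
                estimate=est,
                se=se,
                p=wald_p(est, se),
                scale=scale,
                n_snps=Z.shape[1],
                n_individuals=n,
            )
        if Z.shape[1] > K:
            _, rss = _ols_rss(resid, ZW)
            tss = float(((resid - resid.mean()) ** 2).sum())
            result.sargan = n * (1.0 - rss / tss) if tss > 0 else 0.0
            result.sargan_df = Z.shape[1] - K
            result.sargan_p = float(stats.chi2.sf(result.sargan, result.sargan_df))
    elif stage2 == "logistic":
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("logistic stage 2 needs a binary outcome")
        fit = sm.Logit(y, np.column_stack([Xhat, W])).fit(disp=0, maxiter=200)
        for i, name in enumerate(names):
            est, se = float(fit.params[i]), float(fit.bse[i])
            result.direct_effects[name] = MREstimate(
                method="MVMR two-stage logistic",
                estimate=est,
                se=se,
                p=wald_p(est, se),
                scale="log_odds_per_sd",
                n_snps=Z.shape[1],
                n_individuals=n,
                notes="naive stage-2 SE",
            )
    else:
        raise ValueError(f"stage2 must be 'linear' or 'logistic', got {stage2!r}")
    return result


def conditional_F(
    cohort: IndividualCohort,
    instruments,
    exposures: Sequence = ("exposure", "mediator"),
    covariates: Sequence[str] | np.ndarray | None = ("sex",),
) -> dict:
    """Sanderson–Windmeijer conditional F per exposure.

    For exposure k: 2SLS-regress x_k on the other exposures (instrumented
    by the full set Z), take the structural residual, regress it on Z and
    covariates, and rescale the instruments' F by k_z/(k_z − K + 1).
    """
    Z = _stack_instruments(cohort, instruments)
    X, names = _exposure_matrix(cohort, exposures)
    C = _resolve_covariates(cohort, covariates)
    n, K = X.shape
    kz = Z.shape[1]
    W = np.column_stack([np.ones(n)] + ([C] if C is not None else []))
    ZW = np.column_stack([Z, W])
    out = {}
    for k, name in enumerate(names):
        xk = X[:, k]
        others = np.delete(X, k, axis=1)
        if others.shape[1] == 0:
            out[name] = first_stage_F(xk, Z, W)
            continue
        # 2SLS of x_k on the other exposures
        pi, _, _, _ = np.linalg.lstsq(ZW, np.column_stack([others, W]), rcond=None)
        Dhat = ZW @ pi
        delta, _, _, _ = np.linalg.lstsq(Dhat, xk, rcond=None)
        v = xk - np.column_stack([others, W]) @ delta
        F = first_stage_F(v, Z, W)
        out[name] = F * kz / (kz - K + 1)
    return out
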