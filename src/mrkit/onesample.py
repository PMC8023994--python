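"""One-sample MR on individual-level data.

Instruments are either an unweighted genetic risk score (GRS: the sum of
exposure-increasing allele dosages) or the SNP dosages themselves.  Causal
effects come from two-stage least squares (risk difference per SD for a
binary outcome) and from the two-stage logistic procedure (stage 1: OLS of
the standardized exposure on instruments; stage 2: logistic regression of
the outcome on the predicted exposure), which yields an OR per SD.  The
stage-2 SEs are naive by default — they ignore first-stage uncertainty,
which is negligible for strong instruments but can understate uncertainty
otherwise — with a seeded nonparametric bootstrap as the corrected
alternative.

Diagnostics: first-stage F (instrument strength, conventional cut-off 10),
the Sargan overidentification statistic (n·R² of the 2SLS residuals on the
full instrument set, χ² with #instruments − 1 df for one endogenous
regressor), and a GRS-vs-covariate association scan for confounder checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimates import DiagnosticStats, MREstimate, Z95, wald_p
from .simulate import IndividualCohort
from .sumstats import SNPAssociation

__all__ = [
    "InstrumentSet",
    "build_grs",
    "tsls",
    "two_stage_logistic",
    "instrument_covariate_check",
]


@dataclass(frozen=True)
class InstrumentSet:
    """An ordered instrument list with exposure-raising orientation.

    ``orientation[snp]`` is +1 when the counted (effect) allele raises the
    exposure, −1 when it lowers it (its dosage enters the GRS as 2 − d).
    """

    snp_ids: tuple[str, ...]
    orientation: dict
    label: str = "all"

    def __post_init__(self):
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in instrument set")
        missing = [s for s in self.snp_ids if s not in self.orientation]
        if missing:
            raise ValueError(f"orientation missing for {missing}")

    @classmethod
    def from_sumstats(
        cls, assocs: Sequence[SNPAssociation], label: str = "all"
    ) -> "InstrumentSet":
        """Orient by the sign of each SNP's exposure beta."""
        return cls(
            snp_ids=tuple(a.snp_id for a in assocs),
            orientation={a.snp_id: (1 if a.beta >= 0 else -1) for a in assocs},
            label=label,
        )

    def subset(self, keep: Sequence[str], label: str) -> "InstrumentSet":
        keep = [s for s in self.snp_ids if s in set(keep)]
        return InstrumentSet(tuple(keep), dict(self.orientation), label)


def build_grs(cohort: IndividualCohort, instruments: InstrumentSet) -> np.ndarray:
    """Unweighted GRS: sum of oriented dosages, integer-valued in [0, 2J]."""
    if not instruments.snp_ids:
        raise ValueError("empty instrument set")
    missing = [s for s in instruments.snp_ids if s not in cohort.dosages.columns]
    if missing:
        raise KeyError(f"SNPs absent from cohort dosages: {missing}")
    score = np.zeros(cohort.n)
    n_imputed = 0
    for snp in instruments.snp_ids:
        d = cohort.dosages[snp].to_numpy(float)
        nan = np.isnan(d)
        if nan.any():
            n_imputed += int(nan.sum())
            d = np.where(nan, np.nanmean(d), d)
        score += d if instruments.orientation[snp] > 0 else 2.0 - d
    if n_imputed:
        warnings.warn(f"mean-imputed {n_imputed} missing dosages while building GRS")
    return score


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _as_matrix(a) -> np.ndarray:
    a = np.asarray(a, float)
    return a[:, None] if a.ndim == 1 else a


def _resolve_instruments(cohort: IndividualCohort, instruments) -> np.ndarray:
    if isinstance(instruments, InstrumentSet):
        return cohort.dosages[list(instruments.snp_ids)].to_numpy(float)
    if isinstance(instruments, (list, tuple)) and instruments and isinstance(instruments[0], str):
        return cohort.dosages[list(instruments)].to_numpy(float)
    return _as_matrix(instruments)


def _resolve_trait(cohort: IndividualCohort, trait) -> np.ndarray:
    if isinstance(trait, str):
        if trait == "exposure":
            return cohort.exposure.copy()
        if trait == "mediator":
            return cohort.mediator.copy()
        if trait in cohort.outcomes.columns:
            return cohort.outcomes[trait].to_numpy(float)
        raise KeyError(f"unknown trait {trait!r}")
    return np.asarray(trait, float)


def _resolve_covariates(cohort: IndividualCohort | None, covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, (list, tuple)):
        if not covariates:
            return None
        if isinstance(covariates[0], str):
            return cohort.covariates[list(covariates)].to_numpy(float)
    return _as_matrix(covariates)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ coef
    return coef, float(resid @ resid)


def first_stage_F(
    x: np.ndarray, Z: np.ndarray, W: np.ndarray
) -> float:
    """Partial F for the instruments in x ~ Z + W (W includes the intercept)."""
    _, rss1 = _ols_rss(x, np.column_stack([Z, W]))
    _, rss0 = _ols_rss(x, W)
    k = Z.shape[1]
    dof = len(x) - Z.shape[1] - W.shape[1]
    return ((rss0 - rss1) / k) / (rss1 / dof)


def tsls(
    cohort: IndividualCohort,
    instruments,
    exposure="exposure",
    outcome="oa",
    covariates: Sequence[str] | np.ndarray | None = ("sex",),
) -> tuple[MREstimate, DiagnosticStats]:
    """Two-stage least squares with covariates in both stages.

    For a binary outcome the estimate is a risk difference per SD of
    exposure; for a continuous one it is on the outcome's own scale.  The
    Sargan statistic is reported only when the model is over-identified.
    """
    Z = _resolve_instruments(cohort, instruments)
    x = _resolve_trait(cohort, exposure)
    y = _resolve_trait(cohort, outcome)
    C = _resolve_covariates(cohort, covariates)
    n = len(y)
    W = np.column_stack([np.ones(n)] + ([C] if C is not None else []))
    if Z.shape[1] < 1:
        raise ValueError("at least one instrument required")
    if n <= 1 + W.shape[1]:
        raise ValueError("more regressors than observations")

    Zfull = np.column_stack([Z, W])
    Xfull = np.column_stack([x, W])
    # project the endogenous regressor onto the instrument space
    pi, _, rank, _ = np.linalg.lstsq(Zfull, Xfull, rcond=None)
    if rank < Zfull.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient first stage")
    Xhat = Zfull @ pi
    coef, _, rank_x, _ = np.linalg.lstsq(Xhat, y, rcond=None)
    if rank_x < Xhat.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient second stage")
    resid = y - Xfull @ coef
    dof = n - Xfull.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Xhat.T @ Xhat)
    est, se = float(coef[0]), math.sqrt(cov[0, 0])

    binary = set(np.unique(y)) <= {0.0, 1.0}
    scale = "risk_difference_per_sd" if binary else "linear_per_sd"

    diag = DiagnosticStats(first_stage_F=first_stage_F(x, Z, W))
    k = Z.shape[1]
    if k > 1:
        # Sargan: n * R^2 of the 2SLS residuals on the full instrument set
        _, rss = _ols_rss(resid, Zfull)
        tss = float(((resid - resid.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        diag.sargan = n * r2
        diag.sargan_df = k - 1
        diag.sargan_p = float(stats.chi2.sf(diag.sargan, diag.sargan_df))

    estimate = MREstimate(
        method=f"2SLS ({'GRS' if k == 1 else f'{k} instruments'})",
        estimate=est,
        se=se,
        p=wald_p(est, se),
        scale=scale,
        n_snps=k if k > 1 else None,
        n_individuals=n,
    )
    return estimate, diag


def two_stage_logistic(
    cohort: IndividualCohort,
    instruments,
    exposure="exposure",
    outcome="oa",
    covariates: Sequence[str] | np.ndarray | None = ("sex",),
    *,
    bootstrap: int = 0,
    seed: int | None = None,
) -> MREstimate:
    """The two-stage logistic OR procedure: OR per SD of exposure.

    Stage 1: OLS of the standardized exposure on instruments + covariates.
    Stage 2: logistic regression of the binary outcome on the predicted
    exposure + covariates.  With ``bootstrap=B`` both stages are re-run on
    B seeded resamples and a percentile CI replaces the naive Wald one.
    """
    Z = _resolve_instruments(cohort, instruments)
    x = _resolve_trait(cohort, exposure)
    y = _resolve_trait(cohort, outcome)
    C = _resolve_covariates(cohort, covariates)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("two_stage_logistic needs a binary outcome")
    x = (x - x.mean()) / x.std()  # per-SD scale

    def _fit(Zb, xb, yb, Cb):
        n = len(yb)
        W = np.column_stack([np.ones(n)] + ([Cb] if Cb is not None else []))
        ZW = np.column_stack([Zb, W])
        pi, _, rank, _ = np.linalg.lstsq(ZW, xb, rcond=None)
        if rank < ZW.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient first stage")
        xhat = ZW @ pi
        if np.std(xhat - W @ np.linalg.lstsq(W, xhat, rcond=None)[0]) < 1e-10:
            raise ValueError("predicted exposure has no variance beyond covariates")
        fit = sm.Logit(yb, np.column_stack([xhat, W])).fit(disp=0, maxiter=200)
        return float(fit.params[0]), float(fit.bse[0])

    est, se = _fit(Z, x, y, C)
    ci = None
    notes = "naive stage-2 SE"
    if bootstrap:
        rng = np.random.default_rng(seed)
        n = len(y)
        draws = []
        for _ in range(bootstrap):
            idx = rng.integers(0, n, n)
            try:
                b, _ = _fit(Z[idx], x[idx], y[idx], None if C is None else C[idx])
            except (np.linalg.LinAlgError, ValueError):
                continue
            draws.append(b)
        draws = np.asarray(draws)
        se = float(draws.std(ddof=1))
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
        notes = f"bootstrap SE/percentile CI ({len(draws)} resamples)"
    return MREstimate(
        method="two-stage logistic",
        estimate=est,
        se=se,
        p=wald_p(est, se),
        scale="log_odds_per_sd",
        n_snps=Z.shape[1] if Z.shape[1] > 1 else None,
        n_individuals=len(y),
        ci=ci,
        notes=notes,
    )


def instrument_covariate_check(
    cohort: IndividualCohort,
    grs: np.ndarray,
    covariates: Sequence[str],
) -> pd.DataFrame:
    """Association of each covariate with the GRS (confounder check, IV2).

    Binary covariates are tested by logistic regression on the GRS,
    continuous ones by OLS.  Returns estimate/SE/p per covariate.
    """
    rows = []
    g = np.column_stack([np.asarray(grs, float), np.ones(cohort.n)])
    for name in covariates:
        v = cohort.covariates[name].to_numpy(float)
        if set(np.unique(v)) <= {0.0, 1.0}:
            fit = sm.Logit(v, g).fit(disp=0)
            kind = "logistic"
        else:
            fit = sm.OLS(v, g).fit()
            kind = "linear"
        rows.append(
            {
                "covariate": name,
                "model": kind,
                "estimate": float(fit.params[0]),
                "se": float(fit.bse[0]),
                "p": float(fit.pvalues[0]),
            }
        )
    return pd.DataFrame(rows)
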