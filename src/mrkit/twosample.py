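"""Two-sample summary-data MR estimators and pleiotropy diagnostics.

Per-SNP causal ratios theta_j = Gamma_j / gamma_j (SNP-outcome over
SNP-exposure effect) with first-order SEs sigma_Gamma_j/|gamma_j| are
combined by:

* IVW — the inverse-variance-weighted mean, equivalently a weighted
  zero-intercept regression of Gamma on gamma.  Under multiplicative
  random effects the SE is inflated by sqrt(Q/(J-1)) when Cochran's Q
  exceeds its degrees of freedom; the point estimate is unchanged.
* MR-Egger — the same weighted regression with a free intercept; the
  intercept estimates average directional pleiotropy, valid under the
  InSIDE assumption.  Alleles are first oriented so every gamma_j > 0.
* Weighted median — the 50th weighted percentile of the ordered ratios,
  consistent when up to half the instrument weight is invalid; SE by a
  seeded parametric bootstrap.

Cochran's Q measures heterogeneity of the ratios (excess heterogeneity
suggests pleiotropy); Steiger filtering drops SNPs explaining more trait
variance in the outcome than in the exposure (wrong causal direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimates import DiagnosticStats, MREstimate, wald_p
from .sumstats import HarmonizedSNP, variance_explained

__all__ = [
    "RatioEstimate",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "steiger_filter",
]


@dataclass(frozen=True)
class RatioEstimate:
    """A single SNP's Wald ratio with first-order weight."""

    snp_id: str
    theta: float
    se: float
    p: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2


def wald_ratio(h: HarmonizedSNP, *, second_order: bool = False) -> RatioEstimate:
    """theta_j = Gamma_j/gamma_j with se_j = sigma_Gamma_j/|gamma_j|.

    ``second_order`` adds the exposure-uncertainty term
    theta^2 sigma_gamma^2 / gamma^2 under the square root.
    """
    if h.gamma == 0:
        raise ZeroDivisionError(f"{h.snp_id}: gamma = 0, Wald ratio undefined")
    theta = h.Gamma / h.gamma
    var = (h.se_Gamma / h.gamma) ** 2
    if second_order:
        var += theta**2 * (h.se_gamma / h.gamma) ** 2
    se = math.sqrt(var)
    return RatioEstimate(h.snp_id, theta, se, wald_p(theta, se))


def _ratios(snps: Sequence[HarmonizedSNP] | Sequence[RatioEstimate], **kw) -> list[RatioEstimate]:
    out = []
    for s in snps:
        out.append(s if isinstance(s, RatioEstimate) else wald_ratio(s, **kw))
    return out


def cochran_q(ratios: Sequence[RatioEstimate]) -> tuple[float, int, float]:
    """Q = sum w_j (theta_j - theta_ivw)^2, df = J-1, chi-square p."""
    r = list(ratios)
    if len(r) < 2:
        raise ValueError("Cochran's Q needs at least two ratios")
    w = np.array([x.weight for x in r])
    t = np.array([x.theta for x in r])
    est = float(np.sum(w * t) / np.sum(w))
    q = float(np.sum(w * (t - est) ** 2))
    df = len(r) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(
    snps: Sequence[HarmonizedSNP] | Sequence[RatioEstimate],
    *,
    effects_model: str = "auto",
) -> tuple[MREstimate, DiagnosticStats]:
    """Inverse-variance-weighted estimate over per-SNP ratios.

    ``effects_model``: ``"fixed"``, ``"random"`` (multiplicative random
    effects: SE scaled by max(1, sqrt(Q/(J-1)))), or ``"auto"`` (random
    when J >= 2 and Q/(J-1) > 1, else fixed).  The point estimate is the
    same under all three.
    """
    r = _ratios(snps)
    if not r:
        raise ValueError("ivw needs at least one ratio")
    w = np.array([x.weight for x in r])
    t = np.array([x.theta for x in r])
    est = float(np.sum(w * t) / np.sum(w))
    se_fixed = float(np.sum(w)) ** -0.5

    diag = DiagnosticStats()
    scale_factor = 1.0
    model = "fixed"
    if len(r) >= 2:
        q, df, qp = cochran_q(r)
        diag.cochran_q, diag.cochran_q_df, diag.cochran_q_p = q, df, qp
        overdispersed = q / df > 1.0
        if effects_model == "random" or (effects_model == "auto" and overdispersed):
            scale_factor = max(1.0, math.sqrt(q / df))
            model = "multiplicative random"
    se = se_fixed * scale_factor
    est_obj = MREstimate(
        method=f"IVW ({model} effects)",
        estimate=est,
        se=se,
        p=wald_p(est, se),
        scale="log_odds_per_sd",
        n_snps=len(r),
    )
    return est_obj, diag


def _oriented(snps: Sequence[HarmonizedSNP]) -> list[HarmonizedSNP]:
    """Recode alleles so every SNP-exposure effect is positive."""
    out = []
    for h in snps:
        if h.gamma < 0:
            out.append(
                HarmonizedSNP(
                    snp_id=h.snp_id,
                    gamma=-h.gamma,
                    se_gamma=h.se_gamma,
                    Gamma=-h.Gamma,
                    se_Gamma=h.se_Gamma,
                    eaf=None if h.eaf is None else 1.0 - h.eaf,
                    flipped=not h.flipped,
                    n_exposure=h.n_exposure,
                    n_outcome=h.n_outcome,
                )
            )
        else:
            out.append(h)
    return out


def mr_egger(
    snps: Sequence[HarmonizedSNP],
    *,
    constrain_intercept: bool = False,
    floor_scale: bool = False,
) -> tuple[MREstimate, DiagnosticStats]:
    """MR-Egger: weighted regression of Gamma on gamma with a free intercept.

    Weights are 1/sigma_Gamma^2; alleles are oriented so all gamma_j > 0
    first (required for the InSIDE interpretation).  The slope is the
    causal estimate; the intercept is the average directional pleiotropy.
    SEs use the estimated WLS residual scale with a t reference on J-2 df
    (the original formulation, exactly calibrated under no pleiotropy);
    ``floor_scale=True`` floors the scale at 1 as some tooling does, which
    is conservative when the ratios are underdispersed.
    ``constrain_intercept=True`` is a test-only mode that must reproduce
    the IVW estimate.
    """
    h = _oriented(list(snps))
    min_snps = 1 if constrain_intercept else 3
    if len(h) < min_snps:
        raise ValueError(f"MR-Egger needs at least {min_snps} SNPs, got {len(h)}")
    g = np.array([s.gamma for s in h])
    G = np.array([s.Gamma for s in h])
    w = np.array([1.0 / s.se_Gamma**2 for s in h])
    sw = np.sqrt(w)
    X = (sw[:, None] * (g[:, None] if constrain_intercept else np.column_stack([g, np.ones_like(g)])))
    yw = sw * G
    coef, _, _, _ = np.linalg.lstsq(X, yw, rcond=None)
    resid = yw - X @ coef
    dof = len(h) - X.shape[1]
    q_egger = float(resid @ resid)
    phi = q_egger / dof if dof > 0 else 1.0
    if floor_scale:
        phi = max(1.0, phi)
    cov = phi * np.linalg.inv(X.T @ X)

    slope, slope_se = float(coef[0]), math.sqrt(cov[0, 0])
    diag = DiagnosticStats()
    if not constrain_intercept:
        diag.egger_intercept = float(coef[1])
        diag.egger_intercept_se = math.sqrt(cov[1, 1])
        # t reference with J-2 df, matching the small-sample convention
        tstat = diag.egger_intercept / diag.egger_intercept_se
        diag.egger_intercept_p = float(2.0 * stats.t.sf(abs(tstat), dof))
        diag.cochran_q = q_egger
        diag.cochran_q_df = dof
        diag.cochran_q_p = float(stats.chi2.sf(q_egger, dof)) if dof > 0 else None
    p = float(2.0 * stats.t.sf(abs(slope / slope_se), dof)) if dof > 0 else wald_p(slope, slope_se)
    est = MREstimate(
        method="MR-Egger" + (" (intercept constrained)" if constrain_intercept else ""),
        estimate=slope,
        se=slope_se,
        p=p,
        scale="log_odds_per_sd",
        n_snps=len(h),
    )
    return est, diag


def weighted_median(
    snps: Sequence[HarmonizedSNP] | Sequence[RatioEstimate],
    *,
    n_boot: int = 1000,
    seed: int = 20201007,
) -> MREstimate:
    """Weighted median of the per-SNP ratios (valid to 50% invalid weight).

    The point estimate interpolates the 50th percentile of the ordered
    ratios against cumulative normalized weights (with the half-weight
    centering of the standard construction); the SE comes from a seeded
    parametric bootstrap resampling theta_j ~ N(theta_j, se_j).
    """
    r = _ratios(snps)
    if len(r) < 3:
        raise ValueError(f"weighted median needs at least 3 SNPs, got {len(r)}")
    t = np.array([x.theta for x in r])
    s = np.array([x.se for x in r])
    w = np.array([x.weight for x in r])

    def wm(theta: np.ndarray) -> float:
        order = np.argsort(theta)
        th, wt = theta[order], w[order]
        cum = (np.cumsum(wt) - 0.5 * wt) / wt.sum()
        return float(np.interp(0.5, cum, th))

    est = wm(t)
    rng = np.random.default_rng(seed)
    boots = np.array([wm(rng.normal(t, s)) for _ in range(n_boot)])
    se = float(boots.std(ddof=1))
    return MREstimate(
        method="weighted median",
        estimate=est,
        se=se,
        p=wald_p(est, se),
        scale="log_odds_per_sd",
        n_snps=len(r),
        notes=f"parametric bootstrap SE ({n_boot} draws)",
    )


def steiger_filter(
    snps: Sequence[HarmonizedSNP],
    n_exposure: int | None = None,
    n_outcome: int | None = None,
) -> tuple[list[HarmonizedSNP], pd.DataFrame]:
    """Drop SNPs explaining more variance in the outcome than the exposure.

    r² is computed from the t-statistic, r² = t²/(t² + n − 2), on the
    log-odds scale for binary outcomes.  A SNP is excluded only when
    r²_outcome strictly exceeds r²_exposure (ties retained).  Returns the
    retained set and a per-SNP report with both r² values.
    """
    retained, rows = [], []
    for h in snps:
        ne = n_exposure if n_exposure is not None else h.n_exposure
        no = n_outcome if n_outcome is not None else h.n_outcome
        if ne is None or no is None:
            raise ValueError(f"{h.snp_id}: sample sizes needed for Steiger filtering")
        r2_exp = variance_explained(beta=h.gamma, se=h.se_gamma, n=ne)
        r2_out = variance_explained(beta=h.Gamma, se=h.se_Gamma, n=no)
        keep = not (r2_out > r2_exp)
        rows.append(
            {
                "snp_id": h.snp_id,
                "r2_exposure": r2_exp,
                "r2_outcome": r2_out,
                "direction_ok": keep,
            }
        )
        if keep:
            retained.append(h)
    return retained, pd.DataFrame(rows)
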