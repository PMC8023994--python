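"""Canonical simulation scenarios: the study conditions behind the tests.

Each factory freezes one named data-generating condition — hip-OA-like
GRS analysis, pleiotropy stress test, mediation for MVMR, additive
factorial design — so tests, the analysis drivers and the acceptance
checks all draw from the same world.  Baseline log-odds for binary
outcomes are calibrated empirically (large probe cohort) to hit the target
marginal prevalence; calibrated intercepts are cached per condition, so
replicate loops re-use them.

Default effect sizes (rationale in the methods note):

* exposure instruments: the eight published per-allele effects (|gamma|
  0.029-0.113 SD) with synthetic common-variant EAFs;
* causal effect theta = ln(1.35) log-odds per SD for the hip-like outcome
  at 3.2% prevalence; knee-like uses 5.4%;
* confounding: U adds 0.3 SD to the exposure and 0.2 log-odds to the
  outcome — enough to visibly bias observational estimates without
  dominating;
* directional pleiotropy: 0.08 per exposure-raising allele, comparable to
  the largest instrument effect, sized so intercept-based detection has
  substantial power at the replicate sizes used.
"""

from __future__ import annotations

import math
from functools import lru_cache

from .simulate import (
    CohortConfig,
    OutcomeSpec,
    SNPSpec,
    bmi_like_snps,
    calibrate_intercept_empirical,
    igf1_like_snps,
)

HIP_THETA = math.log(1.35)
HIP_PREVALENCE = 0.032
KNEE_PREVALENCE = 0.054
CONFOUNDER_ON_EXPOSURE = 0.3
CONFOUNDER_ON_OUTCOME = 0.2
DIRECTIONAL_ALPHA = 0.08


def _base(
    n: int,
    seed: int,
    *,
    theta: float,
    pleiotropy: float,
    directional: bool,
    confounded: bool,
    outcome_kind: str,
    intercept: float,
    mediator_snps=(),
    mediator_effect: float = 0.0,
    mediator_theta: float = 0.0,
) -> CohortConfig:
    return CohortConfig(
        n_individuals=n,
        snps=igf1_like_snps(alpha=pleiotropy, directional=directional),
        mediator_snps=mediator_snps,
        outcomes=[
            OutcomeSpec(
                name="oa",
                intercept=intercept,
                theta=theta,
                mediator_theta=mediator_theta,
                kind=outcome_kind,
            )
        ],
        mediator_effect=mediator_effect,
        confounder_on_exposure=CONFOUNDER_ON_EXPOSURE if confounded else 0.0,
        confounder_on_outcome=CONFOUNDER_ON_OUTCOME if confounded else 0.0,
        seed=seed,
    )


@lru_cache(maxsize=None)
def _calibrated_intercept(
    theta: float, pleiotropy: float, directional: bool, confounded: bool, prevalence: float
) -> float:
    probe = _base(
        1000,
        seed=0,
        theta=theta,
        pleiotropy=pleiotropy,
        directional=directional,
        confounded=confounded,
        outcome_kind="binary",
        intercept=-3.0,
    )
    return calibrate_intercept_empirical(probe, "oa", prevalence)


def hip_like_config(
    n: int,
    seed: int,
    *,
    theta: float = HIP_THETA,
    prevalence: float = HIP_PREVALENCE,
    pleiotropy: float = 0.0,
    directional: bool = True,
    confounded: bool = True,
) -> CohortConfig:
    """Hip-OA-like binary outcome instrumented by the eight-SNP panel."""
    c = _calibrated_intercept(theta, pleiotropy, directional, confounded, prevalence)
    return _base(
        n,
        seed,
        theta=theta,
        pleiotropy=pleiotropy,
        directional=directional,
        confounded=confounded,
        outcome_kind="binary",
        intercept=c,
    )


def continuous_config(
    n: int,
    seed: int,
    *,
    theta: float = 0.3,
    pleiotropy: float = 0.0,
    directional: bool = True,
    confounded: bool = True,
) -> CohortConfig:
    """Continuous outcome variant (estimator algebra and calibration checks)."""
    return _base(
        n,
        seed,
        theta=theta,
        pleiotropy=pleiotropy,
        directional=directional,
        confounded=confounded,
        outcome_kind="continuous",
        intercept=0.0,
    )


def mediation_config(
    n: int,
    seed: int,
    *,
    theta_direct: float = 0.3,
    mediator_theta: float = 0.3,
    mediator_effect: float = 0.4,
    n_mediator_snps: int = 63,
) -> CohortConfig:
    """Exposure -> mediator -> continuous outcome, with direct effect too.

    The mediator (BMI-like) has its own disjoint instrument panel; the
    univariable estimand is the total effect theta_direct +
    mediator_theta * slope(exposure->mediator in SD units) recorded in the
    cohort truth, while MVMR targets theta_direct.
    """
    return _base(
        n,
        seed,
        theta=theta_direct,
        pleiotropy=0.0,
        directional=True,
        confounded=True,
        outcome_kind="continuous",
        intercept=0.0,
        mediator_snps=bmi_like_snps(n_mediator_snps),
        mediator_effect=mediator_effect,
        mediator_theta=mediator_theta,
    )


def _factorial_snps() -> tuple[list[SNPSpec], list[SNPSpec]]:
    exp = [SNPSpec(snp_id=f"x{j + 1}", eaf=0.4, gamma=0.2) for j in range(8)]
    med = [SNPSpec(snp_id=f"m{j + 1}", eaf=0.35, gamma=0.15) for j in range(20)]
    return exp, med


@lru_cache(maxsize=None)
def _factorial_intercept(theta: float, mediator_theta: float, prevalence: float) -> float:
    exp, med = _factorial_snps()
    probe = CohortConfig(
        n_individuals=1000,
        snps=exp,
        mediator_snps=med,
        outcomes=[OutcomeSpec("oa", -3.0, theta=theta, mediator_theta=mediator_theta)],
        seed=0,
    )
    return calibrate_intercept_empirical(probe, "oa", prevalence)


def factorial_config(
    n: int,
    seed: int,
    *,
    theta: float = 0.4,
    mediator_theta: float = 0.3,
    prevalence: float = KNEE_PREVALENCE,
) -> CohortConfig:
    """Two strong disjoint GRSs with additive log-odds outcome effects.

    Instrument strength is deliberately higher than the biomarker panel's
    (equal per-allele effects, GRS r2 ~ 0.13 and ~0.2) so the four
    median-split categories are well separated at desk-scale n.
    """
    exp, med = _factorial_snps()
    c = _factorial_intercept(theta, mediator_theta, prevalence)
    return CohortConfig(
        n_individuals=n,
        snps=exp,
        mediator_snps=med,
        outcomes=[OutcomeSpec("oa", c, theta=theta, mediator_theta=mediator_theta)],
        mediator_effect=0.0,  # no mediation: two independent exposure axes
        seed=seed,
    )
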