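"""Synthetic individual-level cohorts with the causal structure MR assumes.

The generator draws unlinked biallelic genotypes in Hardy-Weinberg
equilibrium, builds a standardized continuous exposure from per-allele
effects plus a shared confounder, a downstream standardized mediator
(BMI-like, with its own instrument SNPs), and one or more binary outcomes
from a logistic model that may include a causal exposure effect, a mediator
effect, direct (pleiotropic) SNP effects, confounding, and nuisance
covariates.  Everything downstream of data access — observational models,
one-sample and two-sample MR, MVMR, factorial MR — is testable against the
generating truth recorded in each cohort.

Scales
------
* per-allele exposure effects ``gamma`` are in SD units of the exposure,
* the causal effect ``theta`` and all direct effects are log-odds per SD
  (or per allele for the pleiotropic ``alpha``),
* the exposure is standardized after construction; because residual noise
  is sized so the pre-standardization variance is ~1, the realized
  (post-standardization) per-allele effects recorded in the truth record
  differ from the inputs only by the sampling wobble of the realized SD.

A measured-scale, strictly positive exposure (lognormal, median ~21.5 with
a log-scale SD of ~0.26, emulating a serum IGF-1 distribution in nmol/l) is
carried alongside the standardized one so the observational workflow's
log-transform step has realistic input.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .sumstats import SNPAssociation, beta_to_p

__all__ = [
    "SNPSpec",
    "OutcomeSpec",
    "CohortConfig",
    "CohortTruth",
    "IndividualCohort",
    "simulate_cohort",
    "cohort_to_sumstats",
    "calibrate_intercept",
    "write_cohort",
    "read_cohort",
    "igf1_like_snps",
    "bmi_like_snps",
]

DEFAULT_SEED = 20201007

# Measured-scale exposure: lognormal with median 21.5 and log-SD 0.26
# (matches an IQR of roughly 17.6-24.9 around a median of 21.3-21.5).
_MEASURED_MEDIAN = 21.5
_MEASURED_LOG_SD = 0.26

_ALLELES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SNPSpec:
    """One simulated SNP: frequency, per-allele trait effect, direct outcome effect."""

    snp_id: str
    eaf: float
    gamma: float = 0.0  # per-allele effect on its trait (SD units)
    alpha: float = 0.0  # per-allele direct (pleiotropic) effect on outcomes, log-odds
    effect_allele: str = "A"
    other_allele: str = "G"


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome: baseline plus exposure/mediator effects.

    ``kind="binary"`` draws from a logistic model (intercept and effects
    in log-odds); ``kind="continuous"`` adds unit-variance normal noise to
    the same linear predictor (effects per SD of exposure/mediator).
    """

    name: str
    intercept: float = 0.0
    theta: float = 0.0  # per SD exposure (log-odds if binary)
    mediator_theta: float = 0.0  # per SD mediator
    kind: str = "binary"


@dataclass
class CohortConfig:
    n_individuals: int
    snps: Sequence[SNPSpec]
    mediator_snps: Sequence[SNPSpec] = ()
    outcomes: Sequence[OutcomeSpec] = ()
    mediator_effect: float = 0.0  # exposure -> mediator slope (SD/SD)
    confounder_on_exposure: float = 0.0  # SD units per SD of U
    confounder_on_outcome: float = 0.0  # log-odds per SD of U
    n_covariates: int = 1  # continuous nuisance covariates (plus a sex-like binary)
    sex_on_outcome: float = 0.2  # log-odds for the sex-like covariate
    sex_frequency: float = 0.54
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        ids = [s.snp_id for s in list(self.snps) + list(self.mediator_snps)]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in config")
        for s in list(self.snps) + list(self.mediator_snps):
            if not 0.0 < s.eaf < 1.0:
                raise ValueError(f"{s.snp_id}: eaf must lie strictly in (0,1), got {s.eaf}")
        for o in self.outcomes:
            if o.kind not in ("binary", "continuous"):
                raise ValueError(f"outcome {o.name}: unknown kind {o.kind!r}")
            if o.kind == "binary":
                prev = expit(o.intercept)
                if not 0.0 < prev < 0.5:
                    raise ValueError(
                        f"outcome {o.name}: intercept implies null-effect prevalence "
                        f"{prev:.3f}, outside (0, 0.5)"
                    )
        if not 0.0 < self.sex_frequency < 1.0:
            raise ValueError("sex_frequency must lie in (0,1)")


@dataclass
class CohortTruth:
    """The generating configuration plus realized (post-standardization) scales."""

    config: CohortConfig
    sd_exposure_raw: float
    sd_mediator_raw: float
    gamma_realized: dict  # snp_id -> per-allele exposure effect after standardization
    mediator_slope_realized: float  # exposure(SD) -> mediator(SD)
    total_effect: dict  # outcome name -> theta + mediator_theta * realized slope
    prevalence: dict  # outcome name -> empirical case fraction


@dataclass
class IndividualCohort:
    """Genotypes, phenotypes and the truth that generated them."""

    dosages: pd.DataFrame  # individuals x SNPs, values {0,1,2}
    exposure: np.ndarray  # standardized
    exposure_measured: np.ndarray  # strictly positive, lognormal scale
    mediator: np.ndarray  # standardized
    covariates: pd.DataFrame  # 'sex' + continuous cov1..covK
    outcomes: pd.DataFrame  # one binary column per outcome
    confounder: np.ndarray  # latent U (available for oracle checks only)
    truth: CohortTruth

    @property
    def n(self) -> int:
        return len(self.exposure)

    def to_frame(self) -> pd.DataFrame:
        """Phenotype table for regression-style interfaces."""
        df = pd.DataFrame(
            {
                "exposure": self.exposure,
                "exposure_measured": self.exposure_measured,
                "mediator": self.mediator,
            }
        )
        return pd.concat([df, self.covariates, self.outcomes], axis=1)


def calibrate_intercept(
    target_prevalence: float,
    linear_predictor_sd: float,
    *,
    tol: float = 1e-10,
) -> float:
    """Baseline log-odds giving a marginal prevalence under a normal predictor.

    Solves E[expit(c + s·Z)] = K for c with Z ~ N(0,1) by Gauss-Hermite
    quadrature and bisection; with s=0 this is just logit(K).
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie in (0,1)")
    if linear_predictor_sd == 0.0:
        return float(logit(target_prevalence))
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def marginal(c: float) -> float:
        return float(np.sum(weights * expit(c + linear_predictor_sd * nodes)))

    lo, hi = logit(target_prevalence) - 5.0, logit(target_prevalence) + 5.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if marginal(mid) < target_prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _genetic_value(dosages: np.ndarray, effects: np.ndarray) -> np.ndarray:
    return dosages @ effects


def linear_predictor(cohort: IndividualCohort, outcome: str) -> np.ndarray:
    """The realized log-odds linear predictor for one outcome (incl. intercept)."""
    config = cohort.truth.config
    spec = next(o for o in config.outcomes if o.name == outcome)
    alphas = np.array(
        [s.alpha for s in list(config.snps) + list(config.mediator_snps)]
    )
    cov_effects = np.zeros(cohort.covariates.shape[1])
    cov_effects[0] = config.sex_on_outcome
    return (
        spec.intercept
        + spec.theta * cohort.exposure
        + spec.mediator_theta * cohort.mediator
        + cohort.dosages.to_numpy(float) @ alphas
        + config.confounder_on_outcome * cohort.confounder
        + cohort.covariates.to_numpy() @ cov_effects
    )


def calibrate_intercept_empirical(
    config: CohortConfig,
    outcome: str,
    target_prevalence: float,
    *,
    probe_n: int = 400_000,
    probe_seed: int = 11,
) -> float:
    """Baseline log-odds hitting a target marginal prevalence for one outcome.

    Simulates a large probe cohort under ``config``, reconstructs the
    intercept-free linear predictor, and bisects the intercept so the mean
    of expit(c + lp) equals the target.  Accurate to the probe's Monte
    Carlo error (a few 1e-4 at the default probe size).
    """
    if not 0.0 < target_prevalence < 0.5:
        raise ValueError("target prevalence must lie in (0, 0.5)")
    probe_cfg = dataclasses.replace(
        config, n_individuals=probe_n, seed=probe_seed
    )
    probe = simulate_cohort(probe_cfg)
    spec = next(o for o in config.outcomes if o.name == outcome)
    lp0 = linear_predictor(probe, outcome) - spec.intercept
    lo, hi = float(logit(target_prevalence)) - 6.0, float(logit(target_prevalence)) + 6.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + lp0))) < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: CohortConfig) -> IndividualCohort:
    """Draw a cohort under ``config``; bit-reproducible for a given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    exp_snps = list(config.snps)
    med_snps = list(config.mediator_snps)
    all_snps = exp_snps + med_snps
    freqs = np.array([s.eaf for s in all_snps])
    G = rng.binomial(2, freqs, size=(n, len(all_snps))).astype(np.int8)
    dosages = pd.DataFrame(G, columns=[s.snp_id for s in all_snps])
    G_exp = G[:, : len(exp_snps)].astype(float)
    G_med = G[:, len(exp_snps):].astype(float)

    U = rng.standard_normal(n)
    sex = (rng.random(n) < config.sex_frequency).astype(float)
    covs = {"sex": sex}
    for k in range(config.n_covariates):
        covs[f"cov{k + 1}"] = rng.standard_normal(n)
    covariates = pd.DataFrame(covs)

    # exposure: residual noise sized so pre-standardization variance ~ 1
    gam = np.array([s.gamma for s in exp_snps])
    var_gen = float(np.sum(gam**2 * 2 * freqs[: len(exp_snps)] * (1 - freqs[: len(exp_snps)])))
    var_conf = config.confounder_on_exposure**2
    resid_var = 1.0 - var_gen - var_conf
    if resid_var < 0.05:
        raise ValueError(
            f"genetic ({var_gen:.3f}) plus confounder ({var_conf:.3f}) variance "
            "leaves < 5% residual exposure variance; shrink the effects"
        )
    x_raw = (
        _genetic_value(G_exp, gam)
        + config.confounder_on_exposure * U
        + math.sqrt(resid_var) * rng.standard_normal(n)
    )
    sd_x = float(np.std(x_raw))
    x = (x_raw - np.mean(x_raw)) / sd_x
    exposure_measured = _MEASURED_MEDIAN * np.exp(_MEASURED_LOG_SD * x)

    # mediator: exposure slope plus its own instruments
    gam_m = np.array([s.gamma for s in med_snps]) if med_snps else np.zeros(0)
    f_m = freqs[len(exp_snps):]
    var_gen_m = float(np.sum(gam_m**2 * 2 * f_m * (1 - f_m))) if med_snps else 0.0
    resid_var_m = 1.0 - config.mediator_effect**2 - var_gen_m
    if resid_var_m < 0.05:
        raise ValueError("mediator effects leave < 5% residual mediator variance")
    m_raw = (
        config.mediator_effect * x
        + (_genetic_value(G_med, gam_m) if med_snps else 0.0)
        + math.sqrt(resid_var_m) * rng.standard_normal(n)
    )
    sd_m = float(np.std(m_raw)) if n > 1 else 1.0
    mediator = (m_raw - np.mean(m_raw)) / sd_m
    slope_realized = config.mediator_effect / sd_m

    alphas = np.array([s.alpha for s in all_snps])
    cov_effects = np.zeros(covariates.shape[1])
    cov_effects[0] = config.sex_on_outcome  # continuous covariates are pure noise

    outcome_cols = {}
    prevalence = {}
    total_effect = {}
    for spec in config.outcomes:
        lp = (
            spec.intercept
            + spec.theta * x
            + spec.mediator_theta * mediator
            + G.astype(float) @ alphas
            + config.confounder_on_outcome * U
            + covariates.to_numpy() @ cov_effects
        )
        if spec.kind == "binary":
            y = (rng.random(n) < expit(lp)).astype(np.int8)
            prevalence[spec.name] = float(np.mean(y))
        else:
            y = lp + rng.standard_normal(n)
        outcome_cols[spec.name] = y
        total_effect[spec.name] = spec.theta + spec.mediator_theta * slope_realized
    outcomes = pd.DataFrame(outcome_cols)

    truth = CohortTruth(
        config=config,
        sd_exposure_raw=sd_x,
        sd_mediator_raw=sd_m,
        gamma_realized={s.snp_id: s.gamma / sd_x for s in exp_snps},
        mediator_slope_realized=slope_realized,
        total_effect=total_effect,
        prevalence=prevalence,
    )
    return IndividualCohort(
        dosages=dosages,
        exposure=x,
        exposure_measured=exposure_measured,
        mediator=mediator,
        covariates=covariates,
        outcomes=outcomes,
        confounder=U,
        truth=truth,
    )


def _ols_assoc(d: np.ndarray, y: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """Slope and SE for y ~ d + C (C includes the intercept column)."""
    X = np.column_stack([d, C])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    return float(coef[0]), math.sqrt(sigma2 * XtX_inv[0, 0])


def cohort_to_sumstats(
    cohort: IndividualCohort,
    trait: str,
    *,
    snps: Sequence[str] | None = None,
    adjust_covariates: bool = True,
) -> list[SNPAssociation]:
    """Per-SNP association scan of a cohort trait, one record per SNP.

    ``trait`` is ``"exposure"``, ``"mediator"`` or an outcome column name.
    Continuous traits use OLS; binary outcomes use logistic regression
    (betas on the log-odds scale).  Covariates are adjusted for by default.
    Monomorphic SNPs are excluded with a warning.
    """
    if cohort.n < 30:
        raise ValueError("cohort_to_sumstats needs >= 30 individuals")
    if trait == "exposure":
        y = cohort.exposure
        binary = False
    elif trait == "mediator":
        y = cohort.mediator
        binary = False
    elif trait in cohort.outcomes.columns:
        y = cohort.outcomes[trait].to_numpy(float)
        spec = next(o for o in cohort.truth.config.outcomes if o.name == trait)
        binary = spec.kind == "binary"
    else:
        raise KeyError(f"unknown trait {trait!r}")

    snp_ids = list(snps) if snps is not None else list(cohort.dosages.columns)
    spec_by_id = {
        s.snp_id: s
        for s in list(cohort.truth.config.snps) + list(cohort.truth.config.mediator_snps)
    }
    C = np.column_stack(
        [np.ones(cohort.n)]
        + ([cohort.covariates.to_numpy()] if adjust_covariates else [])
    )

    out: list[SNPAssociation] = []
    for snp_id in snp_ids:
        d = cohort.dosages[snp_id].to_numpy(float)
        if d.min() == d.max():
            warnings.warn(f"{snp_id}: monomorphic in sample; association undefined, excluded")
            continue
        if binary:
            import statsmodels.api as sm

            model = sm.Logit(y, np.column_stack([d, C]))
            fit = model.fit(disp=0)
            beta, se = float(fit.params[0]), float(fit.bse[0])
        else:
            beta, se = _ols_assoc(d, y, C)
        spec = spec_by_id.get(snp_id)
        out.append(
            SNPAssociation(
                snp_id=snp_id,
                effect_allele=spec.effect_allele if spec else "A",
                other_allele=spec.other_allele if spec else "G",
                eaf=float(d.mean() / 2.0),
                beta=beta,
                se=se,
                p=beta_to_p(beta, se),
                n=cohort.n,
                trait_type="binary" if binary else "continuous",
            )
        )
    return out


# ---------------------------------------------------------------------------
# default SNP panels


def igf1_like_snps(alpha: float = 0.0, directional: bool = True) -> list[SNPSpec]:
    """Eight exposure instruments with published per-allele effect sizes.

    The per-allele SD effects are the published instrument betas; EAFs are
    synthetic (the source table prints none) — a plausible common-variant
    spread chosen once.  ``alpha`` adds a per-allele direct outcome effect;
    with ``directional`` the direct effect acts on the exposure-increasing
    allele (alpha carries the sign of gamma), the scenario an Egger
    intercept is designed to detect.
    """
    published = [
        ("rs1065656", 0.050),
        ("rs2153960", 0.048),
        ("rs509035", 0.054),
        ("rs646776", -0.029),
        ("rs700753", 0.113),
        ("rs780093", 0.060),
        ("rs934073", 0.035),
        ("rs978458", -0.074),
    ]
    eafs = [0.45, 0.30, 0.40, 0.22, 0.47, 0.39, 0.34, 0.41]
    return [
        SNPSpec(
            snp_id=sid,
            eaf=f,
            gamma=g,
            alpha=(alpha * math.copysign(1.0, g) if directional else alpha),
        )
        for (sid, g), f in zip(published, eafs)
    ]


def bmi_like_snps(n_snps: int = 63, seed: int = 7, gamma_scale: float = 0.025) -> list[SNPSpec]:
    """A mediator instrument panel emulating a BMI GRS's many small effects."""
    rng = np.random.default_rng(seed)
    eafs = rng.uniform(0.1, 0.9, n_snps)
    gammas = gamma_scale * (0.5 + rng.random(n_snps))
    return [
        SNPSpec(snp_id=f"bmi{j + 1}", eaf=float(f), gamma=float(g))
        for j, (f, g) in enumerate(zip(eafs, gammas))
    ]


# ---------------------------------------------------------------------------
# directory round trip


def write_cohort(cohort: IndividualCohort, directory: str | Path) -> None:
    """Write a cohort as a directory of TSVs plus a YAML truth record."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.dosages.to_csv(d / "dosages.tsv", sep="\t", index=False)
    cohort.to_frame().assign(confounder=cohort.confounder).to_csv(
        d / "phenotypes.tsv", sep="\t", index=False
    )
    cfg = dataclasses.asdict(cohort.truth.config)
    cfg["snps"] = [dataclasses.asdict(s) for s in cohort.truth.config.snps]
    cfg["mediator_snps"] = [dataclasses.asdict(s) for s in cohort.truth.config.mediator_snps]
    cfg["outcomes"] = [dataclasses.asdict(o) for o in cohort.truth.config.outcomes]
    truth = {
        "config": cfg,
        "sd_exposure_raw": cohort.truth.sd_exposure_raw,
        "sd_mediator_raw": cohort.truth.sd_mediator_raw,
        "gamma_realized": cohort.truth.gamma_realized,
        "mediator_slope_realized": cohort.truth.mediator_slope_realized,
        "total_effect": cohort.truth.total_effect,
        "prevalence": cohort.truth.prevalence,
    }
    (d / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))


def read_cohort(directory: str | Path) -> IndividualCohort:
    """Round-trip reader for :func:`write_cohort` output."""
    d = Path(directory)
    dosages = pd.read_csv(d / "dosages.tsv", sep="\t")
    pheno = pd.read_csv(d / "phenotypes.tsv", sep="\t")
    truth_raw = yaml.safe_load((d / "truth.yaml").read_text())
    cfg_raw = truth_raw["config"]
    config = CohortConfig(
        n_individuals=cfg_raw["n_individuals"],
        snps=[SNPSpec(**s) for s in cfg_raw["snps"]],
        mediator_snps=[SNPSpec(**s) for s in cfg_raw["mediator_snps"]],
        outcomes=[OutcomeSpec(**o) for o in cfg_raw["outcomes"]],
        mediator_effect=cfg_raw["mediator_effect"],
        confounder_on_exposure=cfg_raw["confounder_on_exposure"],
        confounder_on_outcome=cfg_raw["confounder_on_outcome"],
        n_covariates=cfg_raw["n_covariates"],
        sex_on_outcome=cfg_raw["sex_on_outcome"],
        sex_frequency=cfg_raw["sex_frequency"],
        seed=cfg_raw["seed"],
    )
    truth = CohortTruth(
        config=config,
        sd_exposure_raw=truth_raw["sd_exposure_raw"],
        sd_mediator_raw=truth_raw["sd_mediator_raw"],
        gamma_realized=truth_raw["gamma_realized"],
        mediator_slope_realized=truth_raw["mediator_slope_realized"],
        total_effect=truth_raw["total_effect"],
        prevalence=truth_raw["prevalence"],
    )
    outcome_names = [o.name for o in config.outcomes]
    cov_cols = ["sex"] + [f"cov{k + 1}" for k in range(config.n_covariates)]
    return IndividualCohort(
        dosages=dosages,
        exposure=pheno["exposure"].to_numpy(),
        exposure_measured=pheno["exposure_measured"].to_numpy(),
        mediator=pheno["mediator"].to_numpy(),
        covariates=pheno[cov_cols],
        outcomes=pheno[outcome_names],
        confounder=pheno["confounder"].to_numpy(),
        truth=truth,
    )
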