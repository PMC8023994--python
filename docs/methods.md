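# Methods

## The causal model

All estimators target the effect of a standardized continuous exposure X
(a circulating biomarker) on outcomes Y, using genetic variants G_j as
instruments.  An instrument must (IV1) associate with X, (IV2) be
independent of confounders U of the X–Y relation, and (IV3) affect Y only
through X.  The package's structural model, used both for estimation
assumptions and for simulation, is

    X  = Σ_j γ_j G_j + δ_X U + ε_X            (then standardized)
    M  = λ X + Σ_k γ^M_k G^M_k + ε_M          (mediator, standardized)
    logit P(Y=1) = c + θ X + θ_M M + Σ_j α_j G_j + δ_Y U + covariates

with per-allele exposure effects γ_j (SD units), a causal effect θ
(log-odds per SD), direct (pleiotropic) SNP effects α_j violating IV3
when non-zero, and a shared confounder U violating the observational —
but not the instrumental — analysis.  A continuous-outcome variant
replaces the logistic link with added unit-normal noise, which is the
regime where estimator algebra (2SLS = IVW, Wald identities) is exact.

## Estimators and conventions

**Wald ratio and IVW.** θ_j = Γ_j/γ_j with first-order SE σ_Γj/|γ_j|
(second-order available via flag); IVW is the w_j = 1/se_j²-weighted mean.
The default effects model is multiplicative random effects when J ≥ 2 and
Q/(J−1) > 1, else fixed; the SE is inflated by √(Q/(J−1)), never changing
the point estimate.  Cochran's Q uses the fixed-effect weights.

**MR-Egger.** Weighted least squares of Γ on γ with a free intercept,
weights 1/σ_Γ², after reorienting alleles so every γ_j > 0 (required for
the InSIDE interpretation).  SEs use the estimated WLS residual scale with
a t reference on J−2 df — the original formulation, whose intercept test
is exactly sized under no pleiotropy (measured 6.2% at nominal 5% over
500 null replicates).  `floor_scale=True` reproduces the convention of
flooring the scale at 1, which is conservative when ratios are
underdispersed (measured ~0.8% under the same null).  A test-only
`constrain_intercept` mode reproduces IVW exactly.

**Weighted median.** Ratios are ordered; the estimate interpolates the
50th percentile of cumulative normalized weights with half-weight
centering.  The SE is a seeded parametric bootstrap (default 1000 draws of
θ_j ~ N(θ_j, se_j)); deterministic given the seed.

**Two-stage least squares.** Closed form with covariates entering both
stages jointly (partialling before or after is algebraically equivalent
for the coefficient; joint entry is implemented).  SEs use the
conventional IV variance σ̂²(X̂ᵀX̂)⁻¹ with n−p residual dof.  First-stage
F is the partial F of the instruments.  Sargan: n·R² from regressing the
2SLS residuals on the full instrument set, χ² with (#instruments −
#endogenous) df, reported only when over-identified.  The implementation
is cross-checked against `statsmodels`' sandbox IV2SLS in the tests.

**Two-stage logistic OR.** Stage 1 regresses the standardized exposure on
instruments + covariates; stage 2 is a logistic fit of the outcome on the
predicted exposure + covariates.  The default SE is the naive stage-2 SE
(it ignores first-stage uncertainty, negligible for strong instruments);
`bootstrap=B` re-runs both stages on B seeded resamples and reports a
percentile CI.  All internal arithmetic is on the log-odds scale; ORs are
exponentiated only at the reporting layer.

**MVMR and conditional F.** Stage 1 fits each exposure on the full
instrument set; stage 2 is linear 2SLS or logistic on all predicted
exposures, each coefficient a direct effect conditional on the others.
The Sanderson–Windmeijer conditional F for exposure k 2SLS-regresses x_k
on the other exposures, regresses the structural residual on the
instruments, and rescales the F by k_z/(k_z − K + 1), K the number of
exposures (the published df adjustment; variants differ in this constant,
and the implemented one reduces exactly to the ordinary first-stage F
when K = 1).

**Harmonization.** Outcome records whose effect allele matches the
exposure's other allele (directly or as strand complement) have beta and
EAF flipped.  Palindromic SNPs (A/T, G/C) are dropped when EAF ∈
[0.42, 0.58] (or when EAF is unknown) and otherwise aligned by frequency.
Records may omit EAF and the non-effect allele — common in published
tables — in which case only exact effect-allele matches harmonize.

**Beta reconstruction and Steiger r².** From a two-sided p:
z = ±Φ⁻¹(1−p/2), se = 1/√(2f(1−f)(n+z²)), β = z·se.  Variance explained
is r² = t²/(t²+n−2); for binary traits this is evaluated on the log-odds
scale — an approximation to a liability r², adequate because Steiger
filtering only compares the two r² values ordinally; a SNP is excluded
only when r²_outcome strictly exceeds r²_exposure.

**Observational models.** The biomarker is ln-transformed internally; the
coefficient is multiplied by ln 2 before exponentiation (OR per doubling),
which is numerically identical to log2-transforming the data but keeps one
canonical scale.  Wald CIs and p-values; no multiple-testing correction
(the outcomes analysed together are highly correlated).

**Power.** Binary-outcome NCP approximation
power = Φ(|ln OR|·√(n·r²·K(1−K)) − z_{1−α/2}), the form used by the mRnd
web calculator; the formula is exposed directly so its constants can be
substituted.

## The synthetic-data generator

Genotypes are unlinked and in Hardy–Weinberg equilibrium (instrument
panels are LD-clumped in practice, so independence is the intended
regime); dosages are hard calls in {0,1,2}.  Residual noise is sized so
the exposure's pre-standardization variance is ≈1, making the γ inputs
interpretable as per-allele SD effects; the realized post-standardization
effects are recorded in each cohort's truth record.  Binary outcomes use
a logistic (not liability-threshold) link, matching the estimators
downstream; baseline log-odds are calibrated by bisection against a
large probe cohort (400,000 draws), accurate to a few 10⁻⁴ in prevalence.
The default seed is 20201007 and is recorded in all outputs.

Default study conditions (`mrkit.scenarios`):

* eight exposure instruments with the published per-allele effects
  (|γ| 0.029–0.113 SD).  The source table prints no allele frequencies,
  so the EAFs are synthetic — a fixed plausible common-variant spread
  (0.22–0.47) chosen once;
* hip-like outcome: θ = ln 1.35 at 3.2% prevalence; knee-like: 5.4%;
* confounding δ_X = 0.3 SD, δ_Y = 0.2 log-odds — enough to visibly bias
  the observational logistic fit while leaving IV estimates consistent;
* directional pleiotropy: α = 0.08 per exposure-raising allele (α_j
  carries the sign of γ_j, the configuration an Egger intercept is
  designed to detect).  The magnitude — comparable to the largest γ — was
  fixed a priori so the intercept test has substantial power at the
  replicate sizes used below;
* mediation scenario: direct θ = 0.3, exposure→mediator slope 0.4,
  mediator→outcome 0.3, with a disjoint 63-SNP mediator panel of small
  effects, so total and direct effects differ by ≈0.12;
* factorial scenario: two deliberately strong disjoint panels (GRS r²
  ≈ 0.13 and ≈ 0.2) with additive log-odds effects 0.4 and 0.3, so the
  four median-split categories are well separated at n ≈ 10⁵.

What the generator does *not* emulate: linkage disequilibrium, imputation
(non-integer) dosages, population stratification, assay error in the
biomarker, selection/survivor bias, and ICD-based phenotype
misclassification.  Passing tests therefore demonstrate estimator
correctness under the assumed causal structure, not robustness to those
real-data complications.

## Problem sizes and numerical choices

The replicate studies run at deliberately modest sizes chosen to keep the
whole suite quick while leaving Monte-Carlo error small relative to the
effects tested: parameter recovery uses 200 replicates of n = 20,000;
diagnostic calibration 500 null (200 pleiotropic) replicates of
n = 10,000 with a continuous outcome so every fit is closed-form;
mediation recovery 200 replicates of n = 5,000 with single-shot
conditional-F checks at n = 50,000; factorial analyses one cohort of
n = 120,000.  Estimator-equivalence checks (2SLS vs IVW within 1%) use
n = 50,000, where the asymptotic identity holds comfortably.

Degenerate inputs fail loudly rather than silently: non-positive
exposures, rank-deficient stages, constant GRSs, empty factorial
categories, monomorphic SNPs (excluded with a warning from summary
scans), γ = 0 Wald ratios.  p-values computed from extreme z-scores are
floored at 10⁻³⁰⁰; the reader's z/p cross-check warns (never fails) at
>10% relative disagreement, since published tables round SEs hard.
Missing dosages are mean-imputed per SNP with a logged count, the
convention for imputed-dosage biobank data.

## Known limitations

Naive two-stage-logistic SEs understate uncertainty when instruments are
weak (use the bootstrap); the logistic estimand is non-collapsible, so at
higher prevalences the two-stage logistic mean drifts slightly from the
generating θ (at 3.2% prevalence the measured bias is well within
Monte-Carlo error); no LIML/GMM or weak-instrument-robust inference; no
MR-PRESSO/mode-based/contamination-mixture estimators; no LD-aware IVW;
summary-data MVMR is out of scope (the multivariable analysis here is
one-sample only).
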