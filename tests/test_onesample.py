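"""One-sample MR: GRS construction, 2SLS, two-stage logistic, diagnostics."""

import math

import numpy as np
import pytest

from mrkit.onesample import (
    InstrumentSet,
    build_grs,
    instrument_covariate_check,
    tsls,
    two_stage_logistic,
)
from mrkit.scenarios import hip_like_config
from mrkit.simulate import cohort_to_sumstats, simulate_cohort
from mrkit.sumstats import harmonize_tables
from mrkit.twosample import ivw, wald_ratio


@pytest.fixture(scope="module")
def exposure_stats(continuous_cohort, snp_ids):
    return cohort_to_sumstats(continuous_cohort, "exposure", snps=snp_ids)


@pytest.fixture(scope="module")
def instruments(exposure_stats):
    return InstrumentSet.from_sumstats(exposure_stats)


class TestBuildGRS:
    def test_all_increasing_homozygote_scores_2j(self, continuous_cohort, instruments):
        grs = build_grs(continuous_cohort, instruments)
        J = len(instruments.snp_ids)
        assert grs.min() >= 0 and grs.max() <= 2 * J
        assert np.allclose(grs, np.round(grs))

    def test_negative_beta_snp_counted_reversed(self, continuous_cohort, instruments):
        # rs978458's exposure beta is negative: its dosage enters as 2 - d
        iset = instruments.subset(["rs978458"], "single")
        assert iset.orientation["rs978458"] == -1
        grs = build_grs(continuous_cohort, iset)
        d = continuous_cohort.dosages["rs978458"].to_numpy(float)
        np.testing.assert_allclose(grs, 2.0 - d)
        # and the oriented score must correlate positively with the exposure
        assert np.corrcoef(grs, continuous_cohort.exposure)[0, 1] > 0

    def test_empty_instrument_set_rejected(self, continuous_cohort):
        with pytest.raises(ValueError):
            build_grs(continuous_cohort, InstrumentSet((), {}))

    def test_missing_dosages_mean_imputed(self, continuous_cohort, instruments):
        cohort = continuous_cohort
        snp = instruments.snp_ids[0]
        original = cohort.dosages[snp].copy()
        try:
            cohort.dosages.loc[:9, snp] = np.nan
            with pytest.warns(UserWarning, match="mean-imputed 10"):
                grs = build_grs(cohort, instruments)
            assert np.isfinite(grs).all()
        finally:
            cohort.dosages[snp] = original


class TestTSLS:
    def test_recovers_causal_effect_with_confounding(self, continuous_cohort, instruments):
        grs = build_grs(continuous_cohort, instruments)
        est, diag = tsls(continuous_cohort, grs, "exposure", "oa", ("sex",))
        theta = continuous_cohort.truth.config.outcomes[0].theta
        assert est.estimate == pytest.approx(theta, abs=2 * est.se)
        assert diag.first_stage_F > 10
        assert diag.sargan is None  # exactly identified

    def test_observational_regression_is_biased_but_iv_is_not(self, continuous_cohort, instruments):
        # same cohort: OLS of outcome on exposure picks up the confounder
        c = continuous_cohort
        theta = c.truth.config.outcomes[0].theta
        y = c.outcomes["oa"].to_numpy()
        X = np.column_stack([c.exposure, np.ones(c.n)])
        ols = np.linalg.lstsq(X, y, rcond=None)[0][0]
        assert abs(ols - theta) > 0.03  # confounding bias, >> IV standard error
        est, _ = tsls(c, build_grs(c, instruments), "exposure", "oa", ("sex",))
        assert abs(est.estimate - theta) < 3 * est.se

    def test_single_instrument_equals_wald_ratio(self, continuous_cohort, snp_ids):
        est, diag = tsls(continuous_cohort, snp_ids[:1], "exposure", "oa", None)
        h = harmonize_tables(
            cohort_to_sumstats(continuous_cohort, "exposure", snps=snp_ids[:1],
                               adjust_covariates=False),
            cohort_to_sumstats(continuous_cohort, "oa", snps=snp_ids[:1],
                               adjust_covariates=False),
        )
        assert est.estimate == pytest.approx(wald_ratio(h[0]).theta, rel=1e-9)
        assert diag.sargan is None

    def test_overidentified_model_reports_sargan(self, continuous_cohort, snp_ids):
        _, diag = tsls(continuous_cohort, snp_ids, "exposure", "oa", ("sex",))
        assert diag.sargan is not None and diag.sargan >= 0
        assert diag.sargan_df == len(snp_ids) - 1
        assert 0 <= diag.sargan_p <= 1

    def test_matches_reference_iv_implementation(self, continuous_cohort, snp_ids):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        c = continuous_cohort
        W = np.column_stack([np.ones(c.n), c.covariates[["sex"]].to_numpy()])
        X = np.column_stack([c.exposure, W])
        Z = np.column_stack([c.dosages[snp_ids].to_numpy(float), W])
        ref = IV2SLS(c.outcomes["oa"].to_numpy(), X, instrument=Z).fit()
        est, _ = tsls(c, snp_ids, "exposure", "oa", ("sex",))
        assert est.estimate == pytest.approx(ref.params[0], rel=1e-10)
        assert est.se == pytest.approx(ref.bse[0], rel=1e-6)

    def test_grs_beats_median_single_snp_first_stage_F(self, continuous_cohort, instruments):
        grs = build_grs(continuous_cohort, instruments)
        _, diag_grs = tsls(continuous_cohort, grs, "exposure", "oa", ("sex",))
        single_Fs = []
        for snp in instruments.snp_ids:
            _, d = tsls(continuous_cohort, [snp], "exposure", "oa", ("sex",))
            single_Fs.append(d.first_stage_F)
        assert diag_grs.first_stage_F > np.median(single_Fs)

    def test_agrees_with_ivw_on_derived_sumstats(self, continuous_cohort, snp_ids):
        est, _ = tsls(continuous_cohort, snp_ids, "exposure", "oa", ("sex",))
        h = harmonize_tables(
            cohort_to_sumstats(continuous_cohort, "exposure", snps=snp_ids),
            cohort_to_sumstats(continuous_cohort, "oa", snps=snp_ids),
        )
        ivw_est, _ = ivw(h, effects_model="fixed")
        assert ivw_est.estimate == pytest.approx(est.estimate, rel=0.01)


class TestTwoStageLogistic:
    @pytest.fixture(scope="class")
    def binary_cohort(self):
        return simulate_cohort(hip_like_config(30_000, seed=77))

    def test_recovers_log_odds_effect(self, binary_cohort):
        cfg = binary_cohort.truth.config
        stats = cohort_to_sumstats(binary_cohort, "exposure",
                                   snps=[s.snp_id for s in cfg.snps])
        grs = build_grs(binary_cohort, InstrumentSet.from_sumstats(stats))
        est = two_stage_logistic(binary_cohort, grs, "exposure", "oa", ("sex",))
        assert est.scale == "log_odds_per_sd"
        assert est.estimate == pytest.approx(math.log(1.35), abs=3 * est.se)

    def test_bootstrap_ci_reproducible_and_ordered(self, binary_cohort):
        cfg = binary_cohort.truth.config
        stats = cohort_to_sumstats(binary_cohort, "exposure",
                                   snps=[s.snp_id for s in cfg.snps])
        grs = build_grs(binary_cohort, InstrumentSet.from_sumstats(stats))
        a = two_stage_logistic(binary_cohort, grs, "exposure", "oa", ("sex",),
                               bootstrap=40, seed=3)
        b = two_stage_logistic(binary_cohort, grs, "exposure", "oa", ("sex",),
                               bootstrap=40, seed=3)
        assert a.ci == b.ci
        assert a.ci[0] < a.estimate < a.ci[1]

    def test_zero_variance_instrument_rejected(self, binary_cohort):
        # a constant GRS duplicates the intercept: degenerate either way
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            two_stage_logistic(
                binary_cohort, np.ones(binary_cohort.n), "exposure", "oa", ("sex",)
            )

    def test_continuous_outcome_rejected(self, continuous_cohort, snp_ids):
        with pytest.raises(ValueError, match="binary"):
            two_stage_logistic(continuous_cohort, snp_ids, "exposure", "oa")


class TestInstrumentCovariateCheck:
    def test_independent_covariate_not_associated(self, continuous_cohort, instruments):
        grs = build_grs(continuous_cohort, instruments)
        table = instrument_covariate_check(continuous_cohort, grs, ["cov1"])
        assert table.loc[0, "p"] > 0.001  # cov1 is pure noise in the generator

    def test_downstream_covariate_detected(self, continuous_cohort, instruments):
        c = continuous_cohort
        grs = build_grs(c, instruments)
        c.covariates["downstream"] = c.exposure + 0.5 * np.random.default_rng(0).standard_normal(c.n)
        try:
            table = instrument_covariate_check(c, grs, ["downstream"])
            assert table.loc[0, "p"] < 1e-6
        finally:
            c.covariates.drop(columns="downstream", inplace=True)

    def test_empty_covariate_list(self, continuous_cohort, instruments):
        grs = build_grs(continuous_cohort, instruments)
        assert instrument_covariate_check(continuous_cohort, grs, []).empty
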