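"""Multivariable MR: direct effects, conditional instrument strength."""

import numpy as np
import pytest

from mrkit.mvmr import conditional_F, mvmr_tsls
from mrkit.onesample import InstrumentSet, build_grs, tsls
from mrkit.scenarios import mediation_config
from mrkit.simulate import cohort_to_sumstats, simulate_cohort


@pytest.fixture(scope="module")
def mediated():
    cohort = simulate_cohort(mediation_config(50_000, seed=13))
    cfg = cohort.truth.config
    exp_ids = [s.snp_id for s in cfg.snps]
    med_ids = [s.snp_id for s in cfg.mediator_snps]
    g1 = build_grs(cohort, InstrumentSet.from_sumstats(
        cohort_to_sumstats(cohort, "exposure", snps=exp_ids)))
    g2 = build_grs(cohort, InstrumentSet.from_sumstats(
        cohort_to_sumstats(cohort, "mediator", snps=med_ids)))
    return cohort, g1, g2


class TestMVMRTsls:
    def test_univariable_total_vs_mvmr_direct(self, mediated):
        cohort, g1, g2 = mediated
        total = cohort.truth.total_effect["oa"]
        direct = cohort.truth.config.outcomes[0].theta
        uni, _ = tsls(cohort, g1, "exposure", "oa", ("sex",))
        assert uni.estimate == pytest.approx(total, abs=3 * uni.se)
        res = mvmr_tsls(cohort, [g1, g2], ("exposure", "mediator"), "oa", ("sex",))
        mv = res.direct_effects["exposure"]
        assert mv.estimate == pytest.approx(direct, abs=3 * mv.se)
        # and the two estimands genuinely differ in this design
        assert total - direct > 0.08

    def test_null_mediator_reduces_to_univariable(self):
        cohort = simulate_cohort(mediation_config(30_000, seed=29, mediator_theta=0.0))
        cfg = cohort.truth.config
        g1 = build_grs(cohort, InstrumentSet.from_sumstats(
            cohort_to_sumstats(cohort, "exposure", snps=[s.snp_id for s in cfg.snps])))
        g2 = build_grs(cohort, InstrumentSet.from_sumstats(
            cohort_to_sumstats(cohort, "mediator", snps=[s.snp_id for s in cfg.mediator_snps])))
        uni, _ = tsls(cohort, g1, "exposure", "oa", ("sex",))
        res = mvmr_tsls(cohort, [g1, g2], ("exposure", "mediator"), "oa", ("sex",))
        mv = res.direct_effects["exposure"]
        assert mv.estimate == pytest.approx(uni.estimate, abs=2 * mv.se)

    def test_exposure_order_permutes_results(self, mediated):
        cohort, g1, g2 = mediated
        a = mvmr_tsls(cohort, [g1, g2], ("exposure", "mediator"), "oa", ("sex",))
        b = mvmr_tsls(cohort, [g1, g2], ("mediator", "exposure"), "oa", ("sex",))
        assert a.direct_effects["exposure"].estimate == pytest.approx(
            b.direct_effects["exposure"].estimate
        )
        assert a.direct_effects["mediator"].se == pytest.approx(
            b.direct_effects["mediator"].se
        )

    def test_underidentification_rejected(self, mediated):
        cohort, g1, _ = mediated
        with pytest.raises(ValueError, match="under-identified"):
            mvmr_tsls(cohort, g1, ("exposure", "mediator"), "oa", ("sex",))

    def test_collinear_predicted_exposures_rejected(self, mediated):
        cohort, g1, g2 = mediated
        # the same exposure twice: stage-1 predictions are identical
        with pytest.raises(ValueError, match="collinear"):
            mvmr_tsls(cohort, [g1, g2], ("exposure", "exposure"), "oa", ("sex",))

    def test_logistic_stage2_on_binary_outcome(self):
        from mrkit.scenarios import factorial_config

        cohort = simulate_cohort(factorial_config(30_000, seed=31))
        cfg = cohort.truth.config
        g1 = build_grs(cohort, InstrumentSet.from_sumstats(
            cohort_to_sumstats(cohort, "exposure", snps=[s.snp_id for s in cfg.snps])))
        g2 = build_grs(cohort, InstrumentSet.from_sumstats(
            cohort_to_sumstats(cohort, "mediator", snps=[s.snp_id for s in cfg.mediator_snps])))
        res = mvmr_tsls(cohort, [g1, g2], ("exposure", "mediator"), "oa", ("sex",),
                        stage2="logistic")
        mv = res.direct_effects["exposure"]
        assert mv.scale == "log_odds_per_sd"
        assert mv.estimate == pytest.approx(cfg.outcomes[0].theta, abs=3 * mv.se)


class TestConditionalF:
    def test_single_exposure_reduces_to_first_stage_F(self, mediated):
        cohort, g1, _ = mediated
        from mrkit.onesample import first_stage_F

        cf = conditional_F(cohort, g1, ("exposure",), ("sex",))
        n = cohort.n
        W = np.column_stack([np.ones(n), cohort.covariates[["sex"]].to_numpy()])
        x = (cohort.exposure - cohort.exposure.mean()) / cohort.exposure.std()
        expected = first_stage_F(x, np.asarray(g1, float)[:, None], W)
        assert cf["exposure"] == pytest.approx(expected)

    def test_disjoint_strong_instruments_give_strong_conditional_F(self, mediated):
        cohort, g1, g2 = mediated
        cf = conditional_F(cohort, [g1, g2], ("exposure", "mediator"), ("sex",))
        assert cf["exposure"] > 10 and cf["mediator"] > 10

    def test_proportional_instruments_collapse(self, mediated):
        cohort, g1, _ = mediated
        rng = np.random.default_rng(1)
        g1b = g1 + 0.01 * rng.standard_normal(cohort.n)  # near-copy of the same GRS
        fake_second_exposure = 0.7 * cohort.exposure + 0.3 * rng.standard_normal(cohort.n)
        cf = conditional_F(
            cohort, [g1, g1b], ("exposure", fake_second_exposure), ("sex",)
        )
        strong = conditional_F(cohort, g1, ("exposure",), ("sex",))["exposure"]
        assert cf["exposure"] < 0.05 * strong
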