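"""Summary-data MR estimators: ratios, IVW, Egger, weighted median, Q, Steiger."""

import math

import numpy as np
import pytest

from mrkit.datasets import IGFBP3_SNPS, load_igf1_harmonized
from mrkit.scenarios import continuous_config
from mrkit.simulate import cohort_to_sumstats, simulate_cohort
from mrkit.sumstats import HarmonizedSNP, harmonize_tables
from mrkit.twosample import (
    RatioEstimate,
    cochran_q,
    ivw,
    mr_egger,
    steiger_filter,
    wald_ratio,
    weighted_median,
)


def _h(snp_id, gamma, se_gamma, Gamma, se_Gamma):
    return HarmonizedSNP(snp_id, gamma, se_gamma, Gamma, se_Gamma)


class TestWaldRatio:
    def test_single_intronic_snp_hip(self, hip_harmonized):
        h = next(x for x in hip_harmonized if x.snp_id == "rs978458")
        r = wald_ratio(h)
        assert math.exp(r.theta) == pytest.approx(1.92, abs=0.005)

    def test_published_row_hand_arithmetic(self, hip_harmonized):
        h = next(x for x in hip_harmonized if x.snp_id == "rs780093")
        assert wald_ratio(h).theta == pytest.approx(math.log(1.041) / 0.060, rel=1e-12)

    def test_null_outcome_gives_zero(self):
        assert wald_ratio(_h("s", 0.1, 0.01, 0.0, 0.01)).theta == 0.0

    def test_zero_gamma_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(_h("s", 0.0, 0.01, 0.1, 0.01))

    def test_sign_flips_with_gamma(self):
        up = wald_ratio(_h("s", 0.1, 0.01, 0.05, 0.01))
        down = wald_ratio(_h("s", -0.1, 0.01, 0.05, 0.01))
        assert up.theta == -down.theta and up.se == down.se


class TestIVW:
    def test_single_ratio_equals_wald(self):
        h = _h("s", 0.1, 0.01, 0.05, 0.01)
        est, diag = ivw([h])
        r = wald_ratio(h)
        assert est.estimate == pytest.approx(r.theta)
        assert est.se == pytest.approx(r.se)
        assert diag.cochran_q is None

    def test_equal_weights_average(self):
        rats = [RatioEstimate("a", 0.2, 0.1, 0.5), RatioEstimate("b", 0.4, 0.1, 0.5)]
        est, _ = ivw(rats, effects_model="fixed")
        assert est.estimate == pytest.approx(0.3)

    def test_weight_rescaling_invariance(self):
        rats = [RatioEstimate(f"s{i}", t, s, 0.5)
                for i, (t, s) in enumerate([(0.1, 0.02), (0.3, 0.05), (0.2, 0.01)])]
        scaled = [RatioEstimate(r.snp_id, r.theta, r.se * 3.0, r.p) for r in rats]
        assert ivw(rats, effects_model="fixed")[0].estimate == pytest.approx(
            ivw(scaled, effects_model="fixed")[0].estimate
        )

    def test_random_effects_never_shrinks_se(self, hip_harmonized):
        fixed, _ = ivw(hip_harmonized, effects_model="fixed")
        rand, _ = ivw(hip_harmonized, effects_model="random")
        assert rand.se >= fixed.se
        assert rand.estimate == pytest.approx(fixed.estimate)


class TestCochranQ:
    def test_zero_iff_all_ratios_equal(self):
        same = [RatioEstimate(f"s{i}", 0.25, 0.1 * (i + 1), 0.5) for i in range(4)]
        q, df, p = cochran_q(same)
        assert q == pytest.approx(0.0, abs=1e-12) and df == 3
        differ = [RatioEstimate("a", 0.1, 0.1, 0.5), RatioEstimate("b", 0.4, 0.1, 0.5)]
        assert cochran_q(differ)[0] > 0

    def test_invariant_under_allele_reorientation(self, hip_harmonized):
        q1 = cochran_q([wald_ratio(h) for h in hip_harmonized])[0]
        flipped = [
            HarmonizedSNP(h.snp_id, -h.gamma, h.se_gamma, -h.Gamma, h.se_Gamma)
            for h in hip_harmonized
        ]
        q2 = cochran_q([wald_ratio(h) for h in flipped])[0]
        assert q1 == pytest.approx(q2)

    def test_removing_igfbp3_snps_reduces_heterogeneity(self, hip_harmonized):
        q_all = cochran_q([wald_ratio(h) for h in hip_harmonized])[0]
        kept = [h for h in hip_harmonized if h.snp_id not in IGFBP3_SNPS]
        q_sub = cochran_q([wald_ratio(h) for h in kept])[0]
        assert q_sub < q_all


class TestMREgger:
    def test_exact_linear_case_recovered_to_machine_precision(self):
        c, theta = 0.012, 0.45
        gammas = [0.03, 0.05, 0.08, 0.11]
        hs = [_h(f"s{i}", g, 0.003, c + theta * g, 0.01) for i, g in enumerate(gammas)]
        est, diag = mr_egger(hs)
        assert est.estimate == pytest.approx(theta, abs=1e-10)
        assert diag.egger_intercept == pytest.approx(c, abs=1e-10)

    def test_orientation_makes_result_flip_invariant(self):
        hs = [_h("a", 0.05, 0.003, 0.02, 0.01), _h("b", -0.07, 0.003, -0.01, 0.01),
              _h("c", 0.1, 0.003, 0.05, 0.01)]
        flipped = [HarmonizedSNP(h.snp_id, -h.gamma, h.se_gamma, -h.Gamma, h.se_Gamma)
                   for h in hs]
        assert mr_egger(hs)[0].estimate == pytest.approx(mr_egger(flipped)[0].estimate)

    def test_constrained_intercept_reproduces_ivw(self, hip_harmonized):
        est, _ = mr_egger(hip_harmonized, constrain_intercept=True)
        ivw_est, _ = ivw(hip_harmonized, effects_model="fixed")
        assert est.estimate == pytest.approx(ivw_est.estimate, rel=1e-10)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            mr_egger([_h("a", 0.05, 0.01, 0.02, 0.01), _h("b", 0.07, 0.01, 0.01, 0.01)])


class TestWeightedMedian:
    def test_equal_weight_median(self):
        rats = [RatioEstimate(s, t, 0.1, 0.5) for s, t in zip("abc", (0.1, 0.3, 0.9))]
        est = weighted_median(rats, n_boot=50, seed=1)
        assert est.estimate == pytest.approx(0.3)

    def test_dominant_weight_wins(self):
        rats = [RatioEstimate("a", 0.1, 10.0, 0.5), RatioEstimate("b", 0.7, 1e-4, 0.5),
                RatioEstimate("c", 1.4, 10.0, 0.5)]
        est = weighted_median(rats, n_boot=50, seed=1)
        assert est.estimate == pytest.approx(0.7, abs=1e-3)

    def test_bootstrap_se_is_seed_reproducible(self, hip_harmonized):
        a = weighted_median(hip_harmonized, n_boot=200, seed=5)
        b = weighted_median(hip_harmonized, n_boot=200, seed=5)
        assert a.se == b.se

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            weighted_median([RatioEstimate("a", 0.1, 0.1, 0.5)] * 2)


class TestSteigerFilter:
    def test_published_instruments_produce_zero_exclusions(self, hip_harmonized):
        retained, report = steiger_filter(hip_harmonized, 30_884, 455_221)
        assert len(retained) == len(hip_harmonized)
        assert report["direction_ok"].all()

    def test_tie_is_retained(self):
        h = _h("s", 0.1, 0.01, 0.1, 0.01)  # identical t, same n both sides
        retained, _ = steiger_filter([h], 1000, 1000)
        assert retained == [h]

    def test_reverse_causation_snp_flagged(self):
        # one SNP drives the outcome directly with no exposure effect
        cfg = continuous_config(20_000, seed=9, theta=0.3)
        snps = list(cfg.snps)
        import dataclasses

        snps[0] = dataclasses.replace(snps[0], gamma=0.0, alpha=0.3)
        cfg.snps = snps
        cohort = simulate_cohort(cfg)
        ids = [s.snp_id for s in snps]
        h = harmonize_tables(
            cohort_to_sumstats(cohort, "exposure", snps=ids),
            cohort_to_sumstats(cohort, "oa", snps=ids),
        )
        _, report = steiger_filter(h, cohort.n, cohort.n)
        flagged = report.loc[~report["direction_ok"], "snp_id"].tolist()
        assert snps[0].snp_id in flagged
        assert report["direction_ok"].sum() >= len(snps) - 2
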