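"""Summary-statistics IO, harmonization, beta reconstruction, r²."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrkit.datasets import load_igf1_table
from mrkit.sumstats import (
    SNPAssociation,
    SumstatsError,
    beta_from_p,
    beta_to_p,
    harmonize,
    read_sumstats,
    variance_explained,
)


def _assoc(**kw):
    defaults = dict(
        snp_id="rs1", effect_allele="A", other_allele="C",
        eaf=0.3, beta=0.05, se=0.01, n=10_000,
    )
    defaults.update(kw)
    defaults.setdefault("p", beta_to_p(defaults["beta"], defaults["se"]))
    return SNPAssociation(**defaults)


class TestReadSumstats:
    def test_bundled_instrument_table(self, tmp_path):
        # transcription of the published instrument table: 8 records
        df = load_igf1_table()
        path = tmp_path / "igf1.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning):  # printed SEs are rounded to 1 s.f.
            recs = read_sumstats(
                path, {"beta": "beta_igf1", "se": "se_igf1", "p": "p_igf1"}
            )
        assert len(recs) == 8
        by_id = {r.snp_id: r for r in recs}
        assert by_id["rs700753"].beta == pytest.approx(0.113)
        assert by_id["rs978458"].beta == pytest.approx(-0.074)

    def test_or_scale_reads_log_odds(self, tmp_path):
        path = tmp_path / "out.tsv"
        path.write_text("snp_id\teffect_allele\tbeta\tse\tp\nrs1\tA\t0.953\t0.015\t0.003\n")
        (rec,) = read_sumstats(path, or_scale=True, trait_type="binary")
        assert rec.beta == pytest.approx(math.log(0.953))
        assert rec.se == 0.015
        (rec2,) = read_sumstats(path, or_scale=True, se_on_or_scale=True, trait_type="binary")
        assert rec2.se == pytest.approx(0.015 / 0.953)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("snp_id\teffect_allele\tbeta\tse\tp\n")
        assert read_sumstats(path) == []

    def test_invalid_eaf_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\teffect_allele\teaf\tbeta\tse\tp\n"
            "rs1\tA\t0.5\t0.05\t0.01\t0.001\n"
            "rs2\tA\t1.2\t0.05\t0.01\t0.001\n"
        )
        with pytest.warns(UserWarning, match=r"line 3.*eaf"):
            recs = read_sumstats(path)
        assert [r.snp_id for r in recs] == ["rs1"]
        with pytest.raises(SumstatsError, match="line 3"):
            read_sumstats(path, strict=True)

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        path = tmp_path / "nobeta.tsv"
        path.write_text("snp_id\teffect_allele\tse\tp\nrs1\tA\t0.01\t0.5\n")
        with pytest.raises(SumstatsError, match="beta"):
            read_sumstats(path)


class TestHarmonize:
    def test_outcome_on_other_allele_is_flipped(self):
        exp = _assoc(effect_allele="A", other_allele="G", beta=0.05)
        out = _assoc(effect_allele="G", other_allele="A", beta=0.02, eaf=0.7)
        h = harmonize(exp, out)
        assert h.flipped
        assert h.Gamma == pytest.approx(-0.02)
        assert h.gamma == pytest.approx(0.05)

    def test_identical_alleles_pass_through(self):
        h = harmonize(_assoc(beta=0.05), _assoc(beta=0.02))
        assert not h.flipped
        assert h.Gamma == pytest.approx(0.02)

    def test_strand_complement_recognised(self):
        exp = _assoc(effect_allele="A", other_allele="G")
        out = _assoc(effect_allele="T", other_allele="C", beta=0.02)
        assert not harmonize(exp, out).flipped

    def test_irreconcilable_alleles_raise(self):
        exp = _assoc(effect_allele="A", other_allele="C")
        out = _assoc(effect_allele="A", other_allele="G")
        with pytest.raises(SumstatsError, match="irreconcilable"):
            harmonize(exp, out)

    def test_ambiguous_palindromic_snp_dropped(self):
        exp = _assoc(effect_allele="A", other_allele="T", eaf=0.5)
        out = _assoc(effect_allele="A", other_allele="T", eaf=0.5)
        with pytest.warns(UserWarning, match="palindromic"):
            assert harmonize(exp, out) is None

    def test_palindromic_snp_aligned_by_frequency(self):
        exp = _assoc(effect_allele="A", other_allele="T", eaf=0.2)
        out = _assoc(effect_allele="A", other_allele="T", eaf=0.8, beta=0.02)
        h = harmonize(exp, out)
        assert h.flipped and h.Gamma == pytest.approx(-0.02)

    def test_flip_is_involutive(self):
        # harmonizing the already-flipped outcome record restores the sign
        exp = _assoc(effect_allele="A", other_allele="G", beta=0.05)
        out = _assoc(effect_allele="G", other_allele="A", beta=0.02, eaf=0.7)
        h1 = harmonize(exp, out)
        out_flipped = _assoc(
            effect_allele="A", other_allele="G", beta=-out.beta, eaf=1 - out.eaf
        )
        h2 = harmonize(exp, out_flipped)
        assert not h2.flipped
        assert h2.Gamma == pytest.approx(h1.Gamma)


class TestBetaFromP:
    def test_null_p_gives_zero_beta(self):
        beta, se = beta_from_p(1.0, +1, 0.3, 5000)
        assert beta == 0.0 and se > 0

    def test_hand_arithmetic_z2(self):
        # z = 2, f = 0.5, n = 10000: se = 1/sqrt(0.5*10004)
        p = 2 * stats.norm.sf(2.0)
        beta, se = beta_from_p(p, +1, 0.5, 10_000)
        assert se == pytest.approx(1 / math.sqrt(0.5 * 10_004), rel=1e-12)
        assert beta == pytest.approx(2 / math.sqrt(0.5 * 10_004), rel=1e-9)

    def test_zero_p_rejected_with_advice(self):
        with pytest.raises(SumstatsError, match="z-score"):
            beta_from_p(0.0, +1, 0.5, 1000)

    def test_round_trip_against_regression(self):
        # simulate dosage->trait, regress, reconstruct beta from the p-value
        rng = np.random.default_rng(7)
        n, f, b = 20_000, 0.3, 0.08
        d = rng.binomial(2, f, n).astype(float)
        y = b * d + rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        X = np.column_stack([d, np.ones(n)])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        se = math.sqrt(resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[0, 0])
        p = beta_to_p(coef[0], se)
        beta_rec, _ = beta_from_p(p, math.copysign(1, coef[0]), f, n)
        assert beta_rec == pytest.approx(coef[0], rel=0.05)

    @given(st.floats(1e-12, 1.0, exclude_max=True), st.sampled_from([-1, 1]))
    @settings(deadline=None, max_examples=50)
    def test_p_round_trip(self, p, sign):
        beta, se = beta_from_p(p, sign, 0.25, 10_000)
        assert beta_to_p(beta, se) == pytest.approx(p, rel=1e-6)


class TestVarianceExplained:
    def test_zero_beta_zero_r2(self):
        assert variance_explained(beta=0.0, se=0.01, n=100) == 0.0

    def test_hand_arithmetic(self):
        r2 = variance_explained(beta=0.1, se=0.01, n=10_000)
        assert r2 == pytest.approx(100 / 10_098, rel=1e-12)

    @given(
        st.floats(-5, 5), st.floats(1e-3, 1.0), st.integers(3, 10**7)
    )
    @settings(deadline=None, max_examples=100)
    def test_bounded_in_unit_interval(self, beta, se, n):
        r2 = variance_explained(beta=beta, se=se, n=n)
        assert 0.0 <= r2 < 1.0

    def test_monotone_in_t_at_fixed_n(self):
        r2s = [variance_explained(beta=b, se=0.01, n=1000) for b in (0.01, 0.05, 0.2)]
        assert r2s == sorted(r2s) and r2s[0] < r2s[-1]
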