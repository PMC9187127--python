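import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdmaf import (
    DataError,
    ValidationError,
    chisq1_neg_log10_sf,
    estimate_freqs,
    format_pvalue,
    hwd_delta,
    hwe_chisq,
    hwe_exact_within_sex,
    hwe_exact_x_joint,
    sdmaf_test_npr,
    sdmaf_test_par,
)
from sdmaf.core_stats import (
    hwe_chisq_stat_delta_form,
    hwe_chisq_stat_expected_form,
)
from sdmaf.genotype_io import SexStratifiedCounts

mpmath.mp.dps = 50


def mp_chisq1_neg_log10_sf(stat):
    """Arbitrary-precision oracle: -log10 erfc(sqrt(x/2))."""
    p = mpmath.erfc(mpmath.sqrt(mpmath.mpf(stat) / 2))
    return float(-mpmath.log10(p))


def npr(female, male, **kw):
    return SexStratifiedCounts(female=female, male=male,
                               male_layout="hemizygous", **kw)


def par(female, male, **kw):
    return SexStratifiedCounts(female=female, male=male,
                               male_layout="diploid", **kw)


triples = st.tuples(st.integers(0, 500), st.integers(0, 500),
                    st.integers(0, 500))


class TestChisq1NegLog10Sf:
    def test_zero_statistic(self):
        assert chisq1_neg_log10_sf(0.0) == 0.0

    def test_p_05_quantile(self):
        assert chisq1_neg_log10_sf(3.841459) == pytest.approx(
            -math.log10(0.05), abs=1e-5)

    @pytest.mark.parametrize("stat", [1.0, 10.0, 100.0, 1600.0, 1e5, 1e7])
    def test_against_mpmath_oracle(self, stat):
        assert chisq1_neg_log10_sf(stat) == pytest.approx(
            mp_chisq1_neg_log10_sf(stat), rel=1e-10)

    def test_deep_tail_beyond_float_underflow(self):
        # p ~ 1e-349: not representable as a double, finite on -log10 scale
        assert chisq1_neg_log10_sf(1600.0) == pytest.approx(349.14, abs=0.01)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            chisq1_neg_log10_sf(-1.0)

    def test_sentinels(self):
        assert chisq1_neg_log10_sf(float("inf")) == float("inf")
        assert math.isnan(chisq1_neg_log10_sf(float("nan")))


class TestEstimateFreqs:
    def test_discussion_toy(self, toy_npr_counts):
        est = estimate_freqs(toy_npr_counts)
        assert est.p_f == pytest.approx(0.2)
        assert est.p_m == pytest.approx(0.5)
        assert est.delta_f == pytest.approx(0.0)
        assert est.delta_m is None

    def test_table_counts(self, top_snp_records):
        rec = top_snp_records[("X-2779827-G-A", "NFE")]
        est = estimate_freqs(rec.counts)
        assert est.p_f == pytest.approx(196 / 39262)

    def test_empty_stratum(self):
        with pytest.raises(DataError):
            estimate_freqs(npr((0, 0, 0), (1, 1)))

    @given(triples)
    def test_delta_within_feasible_range(self, triple):
        n = sum(triple)
        if n == 0:
            return
        d = hwd_delta(triple)
        p = (2 * triple[2] + triple[1]) / (2 * n)
        lo = max(-p * p, -(1 - p) * (1 - p))
        assert lo - 1e-12 <= d <= p * (1 - p) + 1e-12


class TestHwdDelta:
    def test_hwe_exact_proportions(self):
        assert hwd_delta((640, 320, 40)) == pytest.approx(0.0)

    def test_table_male_delta(self, top_snp_records):
        rec = top_snp_records[("X-2779827-G-A", "NFE")]
        assert round(hwd_delta(rec.counts.male), 3) == -0.226

    def test_all_heterozygote(self):
        assert hwd_delta((0, 100, 0)) == pytest.approx(-0.25)

    def test_empty(self):
        with pytest.raises(DataError):
            hwd_delta((0, 0, 0))


class TestSdmafNpr:
    def test_table_afr_p(self, top_snp_records):
        rec = top_snp_records[("X-52861869-T-C", "AFR")]
        res = sdmaf_test_npr(rec.counts)
        assert float(f"{res.p_value:.2e}") == pytest.approx(1.43e-84)

    def test_discussion_toy_statistic(self, toy_npr_counts):
        res = sdmaf_test_npr(toy_npr_counts)
        # T = 0.09 / (0.16/2000 + 0.25/1000) = 272.727...
        assert res.statistic == pytest.approx(272.727272, rel=1e-6)
        assert res.neg_log10_p == pytest.approx(
            mp_chisq1_neg_log10_sf(res.statistic), rel=1e-10)
        assert res.p_value == pytest.approx(2.89e-61, rel=5e-3)

    def test_null_no_difference(self):
        res = sdmaf_test_npr(npr((640, 320, 40), (800, 200)))
        assert res.statistic == pytest.approx(0.0)
        assert res.neg_log10_p == pytest.approx(0.0)

    def test_degenerate_sex_fixed(self):
        # allele fixed differently by sex: zero variance, nonzero numerator
        res = sdmaf_test_npr(npr((100, 0, 0), (0, 100)))
        assert res.degenerate
        assert math.isinf(res.statistic)
        assert math.isinf(res.neg_log10_p)

    def test_wrong_layout_rejected(self, top_snp_records):
        rec = top_snp_records[("X-2779827-G-A", "NFE")]
        with pytest.raises(ValidationError):
            sdmaf_test_npr(rec.counts)


class TestSdmafPar:
    def test_table_nfe_sdmaf(self, top_snp_records):
        rec = top_snp_records[("X-2779827-G-A", "NFE")]
        res = sdmaf_test_par(rec.counts)
        assert round(res.sdmaf, 3) == -0.475

    def test_table_afr_par2(self, top_snp_records):
        rec = top_snp_records[("X-155712209-T-G", "AFR")]
        res = sdmaf_test_par(rec.counts)
        assert round(res.sdmaf, 3) == -0.487

    def test_identical_triples_null(self):
        res = sdmaf_test_par(par((30, 20, 50), (30, 20, 50)))
        assert res.sdmaf == 0.0
        assert res.statistic == pytest.approx(0.0)

    def test_zero_hwd_equals_classical_wald(self):
        # with delta_f = delta_m = 0 the statistic is the classical
        # two-sample proportion Wald chi-square
        f, m = (360, 480, 160), (250, 500, 250)  # p=0.4, p=0.5, deltas 0
        res = sdmaf_test_par(par(f, m))
        pf, pm, nf, nm = 0.4, 0.5, 1000, 1000
        wald = (pf - pm) ** 2 / (pf * (1 - pf) / (2 * nf)
                                 + pm * (1 - pm) / (2 * nm))
        assert res.statistic == pytest.approx(wald, rel=1e-12)


@st.composite
def polymorphic_triples(draw):
    t = draw(triples)
    n = sum(t)
    nA = 2 * t[2] + t[1]
    if n == 0 or nA == 0 or nA == 2 * n:
        return (10, 30, 10)
    return t


class TestHweChisq:
    def test_table_female_p(self, top_snp_records):
        rec = top_snp_records[("X-52861869-T-C", "NFE")]
        res = hwe_chisq(rec.counts, "female")
        assert round(res.delta, 3) == -0.018
        assert float(f"{res.p_value:.2e}") == pytest.approx(1.45e-103)

    def test_exact_hw_proportions_statistic_zero(self):
        c = par((640, 320, 40), (10, 10, 10))
        res = hwe_chisq(c, "female")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.neg_log10_p == pytest.approx(0.0, abs=1e-12)

    def test_forms_agree_on_example(self):
        t = (30, 20, 50)
        assert hwe_chisq_stat_expected_form(t) == pytest.approx(
            hwe_chisq_stat_delta_form(t), rel=1e-10)

    @given(polymorphic_triples())
    @settings(max_examples=300)
    def test_expected_form_equals_delta_form(self, triple):
        assert hwe_chisq_stat_expected_form(triple) == pytest.approx(
            hwe_chisq_stat_delta_form(triple), rel=1e-10)

    def test_monomorphic_reports_na(self):
        res = hwe_chisq(par((10, 0, 0), (5, 0, 0)), "female")
        assert math.isnan(res.neg_log10_p)

    def test_sex_combined_pools_triples(self):
        c = par((30, 20, 50), (10, 40, 20))
        res = hwe_chisq(c, "sex_combined")
        pooled = (40, 60, 70)
        assert res.delta == pytest.approx(hwd_delta(pooled))
        assert res.n == 170

    def test_male_scope_requires_diploid(self, toy_npr_counts):
        with pytest.raises(ValidationError):
            hwe_chisq(toy_npr_counts, "male")


class TestExactWithinSex:
    def test_monomorphic(self):
        res = hwe_exact_within_sex((25, 0, 0))
        assert res.p_value == 1.0

    def test_two_individuals(self, exact_oracles):
        oracle, _ = exact_oracles
        res = hwe_exact_within_sex((1, 0, 1))
        assert res.p_value == pytest.approx(float(oracle(1, 0, 1)), rel=1e-10)

    def test_exhaustive_small_n(self, exact_oracles):
        oracle, _ = exact_oracles
        for n in range(1, 26):
            for n0 in range(n + 1):
                for n1 in range(n - n0 + 1):
                    t = (n0, n1, n - n0 - n1)
                    got = hwe_exact_within_sex(t).p_value
                    assert got == pytest.approx(float(oracle(*t)), rel=1e-9), t

    def test_large_sample_log_space(self):
        # large counts must not overflow the combinatorics
        res = hwe_exact_within_sex((6000, 2000, 2000))
        assert 0 < res.neg_log10_p < 1e6


class TestExactXJoint:
    def test_discussion_value(self, toy_npr_counts):
        res = hwe_exact_x_joint(toy_npr_counts.female, toy_npr_counts.male)
        assert res.p_value == pytest.approx(6.41876e-61, rel=1e-4)

    def test_no_males_reduces_to_within_sex(self):
        res = hwe_exact_x_joint((30, 20, 10), (0, 0))
        ref = hwe_exact_within_sex((30, 20, 10))
        assert res.neg_log10_p == pytest.approx(ref.neg_log10_p, rel=1e-12)

    def test_small_grid_against_oracle(self, exact_oracles):
        _, oracle = exact_oracles
        rng = np.random.default_rng(7)
        for _ in range(150):
            f = rng.integers(1, 9)
            m = rng.integers(1, 9)
            f2 = rng.integers(0, f + 1)
            f1 = rng.integers(0, f - f2 + 1)
            female = (int(f - f2 - f1), int(f1), int(f2))
            malt = int(rng.integers(0, m + 1))
            male = (int(m - malt), malt)
            got = hwe_exact_x_joint(female, male).p_value
            want = float(oracle(female, male))
            assert got == pytest.approx(want, rel=1e-9), (female, male)

    def test_degenerate_empty(self):
        with pytest.raises(DataError):
            hwe_exact_x_joint((0, 0, 0), (0, 0))


class TestAlleleSwapAntisymmetry:
    @given(st.tuples(st.integers(0, 200), st.integers(0, 200),
                     st.integers(0, 200)),
           st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=200)
    def test_npr(self, female, m_ref, m_alt):
        if sum(female) == 0 or m_ref + m_alt == 0:
            return
        c = npr(female, (m_ref, m_alt))
        a = sdmaf_test_npr(c)
        b = sdmaf_test_npr(c.swapped_alleles())
        assert b.sdmaf == pytest.approx(-a.sdmaf, abs=1e-15)
        if not a.degenerate:
            assert b.statistic == pytest.approx(a.statistic, rel=1e-9)
            assert b.neg_log10_p == pytest.approx(a.neg_log10_p, rel=1e-9)

    @given(st.tuples(st.integers(0, 200), st.integers(0, 200),
                     st.integers(0, 200)),
           st.tuples(st.integers(0, 200), st.integers(0, 200),
                     st.integers(0, 200)))
    @settings(max_examples=200)
    def test_par(self, female, male):
        if sum(female) == 0 or sum(male) == 0:
            return
        c = par(female, male)
        a = sdmaf_test_par(c)
        b = sdmaf_test_par(c.swapped_alleles())
        assert b.sdmaf == pytest.approx(-a.sdmaf, abs=1e-15)
        if not a.degenerate:
            assert b.statistic == pytest.approx(a.statistic, rel=1e-9)


class TestFormatPvalue:
    def test_floor_string(self):
        assert format_pvalue(350.0) == "<1E-300"

    def test_regular(self):
        assert format_pvalue(-math.log10(0.05)) == "5.00E-02"

    def test_na(self):
        assert format_pvalue(float("nan")) == "NA"
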