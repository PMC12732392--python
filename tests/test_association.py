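"""Unit and property tests for the single-variant association statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lupusgrs import (
    GenotypeCounts,
    dominant_association,
    genotype_percentages,
    hwe_test,
    pearson_chi2_2x2,
    reference_gof,
)

counts_strategy = st.builds(
    GenotypeCounts,
    n_hom_ref=st.integers(1, 200),
    n_het=st.integers(1, 200),
    n_hom_alt=st.integers(1, 200),
)


class TestHwe:
    def test_exact_hwe_gives_zero_statistic(self):
        # (81, 18, 1) is exactly N*(p^2, 2pq, q^2) at q = 0.10, N = 100.
        res = hwe_test(GenotypeCounts(81, 18, 1))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.estimated_raf == pytest.approx(0.10)

    @pytest.mark.parametrize("counts", [(109, 111, 26), (119, 82, 15)])
    def test_matches_independent_arithmetic_and_fits_hwe(self, counts):
        """Both study arms fit HWE; chi2 checked against hand arithmetic."""
        n0, n1, n2 = counts
        n = n0 + n1 + n2
        q = (n1 + 2 * n2) / (2 * n)
        expected = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q * q]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
        res = hwe_test(GenotypeCounts(*counts))
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
        assert res.p > 0.05

    def test_maximal_heterozygote_deficit(self):
        # (50, 0, 50): q = 0.5, expected (25, 50, 25) -> chi2 = 25 + 50 + 25.
        res = hwe_test(GenotypeCounts(50, 0, 50))
        assert res.chi2 == pytest.approx(100.0)
        assert res.p < 1e-10

    def test_monomorphic_is_flagged_not_raised(self):
        res = hwe_test(GenotypeCounts(10, 0, 0))
        assert res.monomorphic
        assert res.chi2 == 0.0 and res.p == 1.0

    @given(counts=counts_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_allele_relabeling(self, counts):
        flipped = GenotypeCounts(counts.n_hom_alt, counts.n_het, counts.n_hom_ref)
        assert hwe_test(counts).chi2 == pytest.approx(hwe_test(flipped).chi2, rel=1e-9)


class TestDominantAssociation:
    def test_reference_cohort_table(self, sle_counts, control_counts):
        """The printed dominant-model OR, Woolf CI and uncorrected p reproduce."""
        res = dominant_association(sle_counts, control_counts)
        assert res.table == (137, 109, 97, 119)
        assert round(res.or_estimate, 2) == 1.54
        assert round(res.ci_low, 2) == 1.07
        assert round(res.ci_high, 2) == 2.23
        assert round(res.p, 2) == 0.02
        assert not res.continuity_corrected

    def test_identical_arms_are_null(self):
        c = GenotypeCounts(10, 5, 5)
        res = dominant_association(c, c)
        assert res.or_estimate == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_woolf_interval_against_hand_computation(self):
        """Independent log-scale evaluation of the Woolf formulas."""
        res = dominant_association(GenotypeCounts(20, 20, 10), GenotypeCounts(35, 10, 5))
        a, b, c, d = 30, 20, 15, 35
        or_hand = a * d / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert res.or_estimate == pytest.approx(or_hand, rel=1e-12)
        assert res.ci_low == pytest.approx(or_hand * math.exp(-1.959963984540054 * se), rel=1e-12)
        assert res.ci_high == pytest.approx(or_hand * math.exp(1.959963984540054 * se), rel=1e-12)

    @given(case=counts_strategy, control=counts_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_swapping_arms_inverts_or_and_keeps_chi2(self, case, control):
        fwd = dominant_association(case, control)
        rev = dominant_association(control, case)
        assert rev.or_estimate == pytest.approx(1 / fwd.or_estimate, rel=1e-9)
        assert rev.chi2 == pytest.approx(fwd.chi2, rel=1e-9, abs=1e-12)
        assert rev.p == pytest.approx(fwd.p, rel=1e-9)

    @given(case=counts_strategy, control=counts_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ci_contains_estimate(self, case, control):
        res = dominant_association(case, control)
        assert res.ci_low <= res.or_estimate <= res.ci_high

    def test_ci_narrows_when_cells_scale_up(self, sle_counts, control_counts):
        small = dominant_association(sle_counts, control_counts)
        big = dominant_association(
            GenotypeCounts(109 * 4, 111 * 4, 26 * 4), GenotypeCounts(119 * 4, 82 * 4, 15 * 4)
        )
        assert big.or_estimate == pytest.approx(small.or_estimate, rel=1e-12)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_zero_cell_uses_haldane_correction_and_flags(self):
        res = dominant_association(GenotypeCounts(10, 0, 0), GenotypeCounts(5, 5, 5))
        assert res.continuity_corrected
        assert math.isfinite(res.or_estimate) and res.or_estimate > 0
        assert res.ci_low <= res.or_estimate <= res.ci_high
        assert math.isnan(res.chi2) and math.isnan(res.p)


class TestChi2Core:
    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equals_margins_closed_form(self, a, b, c, d):
        """Expected-count Pearson chi2 equals N(ad-bc)^2 / (margin product)."""
        chi2, _ = pearson_chi2_2x2(a, b, c, d)
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed, rel=1e-10, abs=1e-12)

    def test_empty_margin_is_uninformative(self):
        assert pearson_chi2_2x2(0, 5, 0, 7) == (0.0, 1.0)


class TestPercentages:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((109, 111, 26), (44.3, 45.1, 10.6)),
            ((119, 82, 15), (55.1, 38.0, 6.9)),
            ((1, 0, 0), (100.0, 0.0, 0.0)),
        ],
    )
    def test_printed_precision(self, counts, expected):
        assert genotype_percentages(GenotypeCounts(*counts)) == expected

    @given(counts=counts_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sums_to_100_within_rounding(self, counts):
        assert sum(genotype_percentages(counts)) == pytest.approx(100.0, abs=0.15)


class TestReferenceGof:
    def test_matching_proportions_give_zero(self):
        res = reference_gof(GenotypeCounts(50, 40, 10), (0.5, 0.4, 0.1), "three_genotype")
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_direct_arithmetic_three_genotype(self):
        # Expected (25, 50, 25); chi2 = 75^2/25 + 50^2/50 + 25^2/25 = 300.
        res = reference_gof(GenotypeCounts(100, 0, 0), (0.25, 0.5, 0.25), "three_genotype")
        assert res.chi2 == pytest.approx(300.0)
        assert res.df == 2

    def test_dominant_collapse_has_one_df(self, sle_counts):
        res = reference_gof(sle_counts, (0.533, 0.394, 0.073))
        assert res.mode == "dominant_collapse" and res.df == 1
        three = reference_gof(sle_counts, (0.533, 0.394, 0.073), "three_genotype")
        assert three.df == 2
        assert res.chi2 != pytest.approx(three.chi2)

    def test_low_expected_cell_is_flagged(self):
        res = reference_gof(GenotypeCounts(5, 1, 1), (0.9, 0.09, 0.01), "three_genotype")
        assert res.low_expected

    def test_unnormalised_props_are_normalised(self, sle_counts):
        a = reference_gof(sle_counts, (0.533, 0.394, 0.073))
        b = reference_gof(sle_counts, (53.3, 39.4, 7.3))
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)
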