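"""2x2 statistics against published values, brute force, and scipy."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hlassoc.association import (
    CountTable2x2,
    UndefinedStatisticError,
    associate,
    build_frequency_table,
    category_vs_rest,
    choose_test,
    conditional_mle_or,
    cross_product_or,
    fisher_exact_p,
    pearson_chi2_p,
    rare_partition,
    woolf_ci,
)

# Published rows of the Swedish Pandemrix-NT1 cohort that pin down the
# estimator family: cross-product OR, Woolf CI, uncorrected 1-df chi-square.
PUBLISHED_CHI2_ROWS = [
    # (a, b, c, d), OR 2dp, (ci_low, ci_high) 2dp, p printed
    ((34, 28, 205, 1067), 6.32, (3.75, 10.65), "8.24E-15"),  # DRB5*01:01:01
    ((34, 28, 202, 1070), 6.43, (3.82, 10.84), "4.17E-15"),  # DRB1*15:01:01
    ((38, 24, 265, 1007), 6.02, (3.55, 10.21), "1.13E-13"),  # DQA1*01:02:01
    ((34, 28, 201, 1071), 6.47, (3.84, 10.91), "3.31E-15"),  # DQB1*06:02:01
    ((34, 28, 194, 1078), 6.75, (4.00, 11.38), "6.17E-16"),  # extended anchor
    ((34, 28, 200, 1072), 6.51, (3.86, 10.97), "2.62E-15"),  # DQ haplotype
    ((38, 24, 55, 77), 2.22, (1.20, 4.11), "1.07E-02"),  # DQA1*01:02:01 vs FDR
    ((9, 53, 81, 1191), 2.50, (1.19, 5.24), "1.25E-02"),  # DQA1*03:02 group
]


class TestCrossProductOR:
    @pytest.mark.parametrize("cells,or2,_ci,_p", PUBLISHED_CHI2_ROWS)
    def test_reproduces_published_rows(self, cells, or2, _ci, _p):
        assert round(cross_product_or(CountTable2x2(*cells)), 2) == or2

    @pytest.mark.parametrize("k", [1, 5, 17])
    def test_symmetric_table_is_one(self, k):
        assert cross_product_or(CountTable2x2(k, k, k, k)) == 1.0

    def test_group_swap_inverts(self):
        t = CountTable2x2(7, 21, 126, 944)
        swapped = CountTable2x2(126, 944, 7, 21)
        assert cross_product_or(t) * cross_product_or(swapped) == pytest.approx(1.0)

    def test_zero_denominator_signals_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cross_product_or(CountTable2x2(3, 0, 5, 7))


class TestWoolfCI:
    @pytest.mark.parametrize("cells,_or,ci,_p", PUBLISHED_CHI2_ROWS)
    def test_reproduces_published_bounds(self, cells, _or, ci, _p):
        lo, hi = woolf_ci(CountTable2x2(*cells))
        assert (round(lo, 2), round(hi, 2)) == ci

    def test_symmetric_table_bounds_are_reciprocal(self):
        lo, hi = woolf_ci(CountTable2x2(8, 8, 8, 8))
        assert lo * hi == pytest.approx(1.0)

    def test_width_shrinks_under_common_scaling(self):
        widths = []
        for k in (1, 2, 5, 10):
            lo, hi = woolf_ci(CountTable2x2(4 * k, 6 * k, 5 * k, 5 * k))
            widths.append(math.log(hi) - math.log(lo))
        assert widths == sorted(widths, reverse=True)

    def test_zero_cell_signals_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            woolf_ci(CountTable2x2(0, 10, 5, 5))


class TestPearsonChi2:
    @pytest.mark.parametrize("cells,_or,_ci,p", PUBLISHED_CHI2_ROWS)
    def test_reproduces_published_p_to_three_sig_figs(self, cells, _or, _ci, p):
        assert f"{pearson_chi2_p(CountTable2x2(*cells)):.2E}" == p

    def test_table_at_expectation_gives_p_one(self):
        # margins 20/20, 10/30: expected table exactly (5, 15, 5, 15)
        assert pearson_chi2_p(CountTable2x2(5, 15, 5, 15)) == pytest.approx(1.0)

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        t = CountTable2x2(34, 28, 205, 1067)
        s = CountTable2x2(1067, 205, 28, 34)
        assert pearson_chi2_p(t) == pytest.approx(pearson_chi2_p(s))


class TestFisherExact:
    def test_flat_table(self):
        assert fisher_exact_p(CountTable2x2(1, 1, 1, 1)) == 1.0

    def test_extreme_table_by_hand_enumeration(self):
        # margins 5/5, 5/5: 6 tables, the two extremes weigh 1/252 each
        assert fisher_exact_p(CountTable2x2(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_reproduces_published_small_cell_rows(self):
        assert f"{fisher_exact_p(CountTable2x2(3, 59, 6, 1266)):.2E}" == "6.58E-03"
        assert f"{fisher_exact_p(CountTable2x2(5, 26, 6, 630)):.2E}" == "5.93E-05"

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    @settings(derandomize=True, max_examples=300)
    def test_agrees_with_scipy_route(self, cells):
        a, b, c, d = cells
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        mine = fisher_exact_p(CountTable2x2(a, b, c, d))
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, rel=1e-8)


class TestChooseTest:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((34, 28, 205, 1067), "chi2"),  # min expected ~11
            ((3, 59, 6, 1266), "fisher"),  # expected a ~0.42
            ((0, 10, 0, 10), "fisher"),  # zero column margin
        ],
    )
    def test_expected_cell_rule(self, cells, expected):
        assert choose_test(CountTable2x2(*cells)) == expected

    def test_forced_rules(self):
        t = CountTable2x2(3, 59, 6, 1266)
        assert choose_test(t, "always_chi2") == "chi2"
        assert choose_test(CountTable2x2(34, 28, 205, 1067), "always_fisher") == "fisher"


class TestConditionalMLE:
    def test_matches_published_exact_estimate(self):
        # the one published genotype OR computed conditionally
        assert round(conditional_mle_or(CountTable2x2(5, 26, 6, 630)), 2) == 19.89

    def test_associate_reports_estimator_and_degenerate_cells(self):
        res = associate("x", CountTable2x2(5, 0, 5, 5))  # b = 0: OR undefined
        assert res.or_ is None and res.ci_low is None
        assert res.test_used == "fisher"
        assert 0 < res.p <= 1
        res0 = associate("y", CountTable2x2(0, 10, 5, 5))  # a = 0: OR is 0
        assert res0.or_ == 0.0 and res0.ci_low is None


class TestFrequencyTables:
    def test_carrier_percentages_match_published_cohort(self):
        items = {
            "NT1": [["A"] if i < 30 else ["B"] for i in range(31)],
            "GP": [["A"] if i < 178 else ["B"] for i in range(636)],
        }
        freq = build_frequency_table(items, unit="carriers")
        assert f"{freq.pct('NT1', 'A'):.1f}" == "96.8"
        assert f"{freq.pct('GP', 'A'):.1f}" == "28.0"

    def test_haplotype_slots_count_both_chromosomes(self):
        items = {"G": [["A", "A"], ["A", "B"]]}
        freq = build_frequency_table(items, unit="haplotype_slots")
        assert freq.denominators["G"] == 4
        assert freq.count("G", "A") == 3

    def test_all_identical_cohort_is_single_category_at_100(self):
        freq = build_frequency_table({"G": [["A", "A"]] * 5})
        assert freq.categories() == ["A"]
        assert freq.pct("G", "A") == 100.0

    def test_category_vs_rest_cells(self):
        items = {
            "NT1": [["A", "A"]] * 17 + [["A", "B"]] * 0 + [["B", "B"]] * 14,
            "GP": [["A", "B"]] * 205 + [["B", "B"]] * 431,
        }
        freq = build_frequency_table(items)
        t = category_vs_rest(freq, "A", "NT1", "GP")
        assert (t.a, t.b, t.c, t.d) == (34, 28, 205, 1067)
        with pytest.raises(KeyError):
            category_vs_rest(freq, "missing", "NT1", "GP")

    def test_rare_partition_any_group_and_inclusive_boundary(self):
        items = {
            # 1.6% in the small group, far below 1% in the big one
            "NT1": [["A", "B"]] + [["B", "B"]] * 30,
            "GP": [["A", "B"]] + [["B", "B"]] * 999,
        }
        freq = build_frequency_table(items)
        common, rare = rare_partition(freq, 1.0)
        assert "A" in common and not rare
        # exactly at the threshold is common
        items2 = {"G": [["A", "B"]] + [["B", "B"]] * 49}  # A at exactly 1%
        common2, _ = rare_partition(build_frequency_table(items2), 1.0)
        assert "A" in common2
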