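"""Frequency estimation, G-test of independence, pairwise matrix, regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, chi2_contingency

from tetradgc import (
    TetradCounts,
    control_comparison,
    estimate_frequency,
    g_test_independence,
    pairwise_matrix,
    pool_counts,
    position_regression,
    regression_points,
)
from tetradgc.conversion_stats import format_p, format_sci, round_half_up


def brute_force_g(k1, n1, k2, n2):
    """Independent oracle: explicit-loop 2 * sum O*ln(O/E)."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    row = [sum(r) for r in table]
    col = [table[0][j] + table[1][j] for j in range(2)]
    n = n1 + n2
    g = 0.0
    for i in range(2):
        for j in range(2):
            o = table[i][j]
            if o > 0:
                g += o * math.log(o / (row[i] * col[j] / n))
    return 2.0 * g


class TestEstimate:
    def test_highest_frequency_locus(self, reference):
        est = estimate_frequency(reference["counts"]["424-GC1"])
        assert format_sci(est.adjusted_frequency) == "1.07E-03"
        assert est.meioses_per_conversion == 936

    def test_lowest_frequency_locus(self, reference):
        est = estimate_frequency(reference["counts"]["1659-GC1"])
        assert est.meioses_per_conversion == 5768

    def test_zero_conversions(self):
        est = estimate_frequency(TetradCounts(label="control", n_tetrads=45000, n_31=0))
        assert est.adjusted_frequency == 0.0
        assert est.meioses_per_conversion is None

    def test_adjustment_doubles_exactly(self, reference):
        for c in reference["counts_list"]:
            est = estimate_frequency(c)
            assert est.adjusted_frequency == 2.0 * est.raw_frequency

    def test_saturated_counts_warn(self):
        with pytest.warns(RuntimeWarning, match="exceeds 1"):
            est = estimate_frequency(TetradCounts(label="x", n_tetrads=50, n_31=50))
        assert est.adjusted_frequency == 2.0

    def test_zero_tetrads_rejected(self):
        with pytest.raises(ValueError, match="zero tetrads"):
            estimate_frequency(TetradCounts(label="x", n_tetrads=0, n_31=0))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 500), st.integers(1, 10**6), st.integers(2, 9))
    def test_scale_consistency(self, k, extra, m):
        n = 2 * k + extra  # keep the adjusted frequency in range
        a = estimate_frequency(TetradCounts(label="x", n_tetrads=n, n_31=k))
        b = estimate_frequency(TetradCounts(label="x", n_tetrads=m * n, n_31=m * k))
        assert a.raw_frequency == pytest.approx(b.raw_frequency, rel=1e-12)
        assert a.adjusted_frequency == pytest.approx(b.adjusted_frequency, rel=1e-12)

    def test_half_up_reporting_rule(self):
        # 150910/34 = 4438.5 and 155280/32 = 4852.5 must round up
        assert round_half_up(4438.5) == 4439
        assert round_half_up(4852.5) == 4853


class TestPooling:
    def test_genome_wide_average(self, reference):
        pooled = pool_counts(reference["panel"])
        assert format_sci(pooled.adjusted_frequency) == "3.53E-04"
        assert pooled.meioses_per_conversion == 2833

    def test_single_element_identity(self, reference):
        c = reference["counts"]["567-GC1"]
        assert pool_counts([c]).adjusted_frequency == estimate_frequency(c).adjusted_frequency

    def test_equal_frequencies_pool_to_common_value(self):
        a = TetradCounts(label="a", n_tetrads=10000, n_31=5)
        b = TetradCounts(label="b", n_tetrads=30000, n_31=15)
        assert pool_counts([a, b]).raw_frequency == pytest.approx(5e-4)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_counts([])


class TestGTest:
    def test_similar_loci_not_distinguished(self):
        r = g_test_independence(17, 148886, 17, 150910)
        assert r.p_value == pytest.approx(0.97, abs=0.005)

    def test_identical_groups_give_independence(self):
        r = g_test_independence(12, 1000, 12, 1000)
        assert r.g_statistic == 0.0 and r.p_value == 1.0

    def test_extreme_locus_pair(self):
        # frozen from an expected-counts + chi-square survival oracle
        r = g_test_independence(79, 147848, 13, 149965)
        assert r.g_statistic == pytest.approx(53.549, abs=0.001)
        assert r.p_value == pytest.approx(2.52e-13, rel=0.01)

    def test_reversion_control_value(self):
        r = g_test_independence(0, 45000, 13, 149965)
        assert r.g_statistic == pytest.approx(6.823, abs=0.001)
        assert round(r.p_value, 6) == 0.008998

    def test_degenerate_all_zero_margin(self):
        r = g_test_independence(0, 500, 0, 700)
        assert r.degenerate and r.g_statistic == 0.0 and r.p_value == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            g_test_independence(5, 4, 1, 10)
        with pytest.raises(ValueError):
            g_test_independence(1, 0, 1, 10)

    def test_williams_correction_shrinks_g(self):
        plain = g_test_independence(8, 40, 2, 40)
        corrected = g_test_independence(8, 40, 2, 40, williams=True)
        assert 0 < corrected.g_statistic < plain.g_statistic

    def test_against_brute_force_oracle_bulk(self):
        rng = np.random.default_rng(20260923)
        checked = 0
        while checked < 1000:
            n1, n2 = rng.integers(2, 10**6, size=2)
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            if k1 == 0 and k2 == 0:
                continue
            if k1 == n1 and k2 == n2:
                continue
            r = g_test_independence(k1, int(n1), k2, int(n2))
            g_ref = brute_force_g(k1, int(n1), k2, int(n2))
            assert r.g_statistic == pytest.approx(g_ref, rel=1e-9, abs=1e-12)
            assert r.p_value == pytest.approx(float(chi2.sf(g_ref, 1)), rel=1e-6, abs=1e-300)
            checked += 1

    def test_matches_scipy_log_likelihood_route(self):
        # independent library route on a well-populated table
        obs = np.array([[79, 147848 - 79], [13, 149965 - 13]])
        g_ref, p_ref, _, _ = chi2_contingency(obs, correction=False, lambda_="log-likelihood")
        r = g_test_independence(79, 147848, 13, 149965)
        assert r.g_statistic == pytest.approx(float(g_ref), rel=1e-12)
        assert r.p_value == pytest.approx(float(p_ref), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 200), st.integers(1, 2000), st.integers(0, 200), st.integers(1, 2000))
    def test_symmetries(self, k1, e1, k2, e2):
        n1, n2 = k1 + e1, k2 + e2
        a = g_test_independence(k1, n1, k2, n2)
        swapped_groups = g_test_independence(k2, n2, k1, n1)
        swapped_columns = g_test_independence(n1 - k1, n1, n2 - k2, n2)
        assert a.g_statistic == pytest.approx(swapped_groups.g_statistic, rel=1e-12, abs=1e-12)
        assert a.g_statistic == pytest.approx(swapped_columns.g_statistic, rel=1e-12, abs=1e-12)


class TestPairwiseMatrix:
    def test_symmetric_frame_with_na_diagonal(self, reference):
        m = pairwise_matrix(reference["counts_list"]).p_value_frame()
        assert np.isnan(np.diag(m.values)).all()
        off = ~np.eye(len(m), dtype=bool)
        assert np.allclose(m.values[off], m.values.T[off])

    def test_intra_locus_alleles_indistinguishable(self, reference):
        m = pairwise_matrix(reference["counts_list"])
        assert m.get("1369-GC1", "1369-GC2").p_value == pytest.approx(0.94, abs=0.005)

    def test_raw_not_doubled_counts(self, reference):
        # doubling would roughly double G and break agreement with the
        # published matrix; the 3411 vs 1659 cell pins the choice
        m = pairwise_matrix(reference["counts_list"])
        assert m.get("3411-GC1", "1659-GC1").p_value == pytest.approx(0.009, abs=0.0005)

    def test_input_order_irrelevant(self, reference):
        counts = reference["counts_list"]
        a = pairwise_matrix(counts)
        b = pairwise_matrix(list(reversed(counts)))
        for (x, y), r in a.results.items():
            assert b.get(x, y).p_value == pytest.approx(r.p_value, rel=1e-12)

    def test_requires_two_sets(self, reference):
        with pytest.raises(ValueError, match="two"):
            pairwise_matrix(reference["counts_list"][:1])


class TestControls:
    def test_reversion_control_significantly_below_observed(self, reference):
        ctrl = TetradCounts(label="NFTL-homozygote", n_tetrads=45000, n_31=0)
        cmp = control_comparison(ctrl, reference["counts"]["1659-GC1"])
        assert cmp.result.p_value == pytest.approx(0.008998, abs=5e-7)
        assert "45000" in cmp.report and "149965" in cmp.report

    def test_control_against_pooled_documented_reconstruction(self, reference):
        # the same control against the pooled panel gives a different order
        # of magnitude; kept as documentation that the two comparisons differ
        ctrl = TetradCounts(label="ctrl", n_tetrads=45000, n_31=0)
        pooled = TetradCounts(label="total", n_tetrads=1054024, n_31=186)
        cmp = control_comparison(ctrl, pooled)
        assert cmp.result.p_value == pytest.approx(8e-5, rel=0.05)

    def test_control_equal_to_reference(self):
        c = TetradCounts(label="x", n_tetrads=1000, n_31=4)
        assert control_comparison(c, c).result.p_value == 1.0


class TestRegression:
    def test_no_positional_polarity_detected(self, reference):
        pts = regression_points(reference["alleles"].values(), reference["counts_list"])
        assert len(pts) == 8
        reg = position_regression(pts)
        assert round(reg.r_squared, 3) == 0.038
        assert reg.p_value == pytest.approx(0.645, abs=0.005)

    def test_collinear_points(self):
        reg = position_regression([(1, 2.0), (2, 4.0), (3, 6.0)])
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        reg = position_regression([(1, 5.0), (2, 5.0), (3, 5.0)])
        assert reg.slope == 0.0 and reg.r_squared == 0.0

    def test_identical_positions_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            position_regression([(7, 1.0), (7, 2.0), (7, 3.0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            position_regression([(1, 1.0), (2, 2.0)])


class TestFormatting:
    def test_sci_notation(self):
        assert format_sci(2 * 17 / 148886) == "2.28E-04"

    def test_tiny_p_is_censored_for_display(self):
        assert format_p(3e-16) == "<1E-15"
        assert format_p(0.45) == "0.45"
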