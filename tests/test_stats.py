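"""Accuracy statistics: Wilson CIs, contingency tests, Holm, group comparison."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_matrix
from trichostudy.stats import (accuracy, compare_groups, fisher_exact_2x2,
                               fisher_monte_carlo, holm_adjust, pearson_chi2,
                               wilson_ci)


class TestWilsonCI:
    @pytest.mark.parametrize("k,n,expected", [
        (8, 24, (0.180, 0.533)),
        (2, 25, (0.022, 0.250)),
    ])
    def test_reference_intervals_to_3_decimals(self, k, n, expected):
        lo, hi = wilson_ci(k, n)
        assert round(lo, 3) == expected[0]
        assert round(hi, 3) == expected[1]

    def test_zero_successes_lower_bound_exactly_zero(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_all_successes_upper_bound_exactly_one(self):
        lo, hi = wilson_ci(10, 10)
        assert hi == 1.0 and 0 < lo < 1

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for k, n in [(0, 5), (3, 7), (44, 99), (106, 150), (218, 375)]:
            lo, hi = wilson_ci(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_validation(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 3)


class TestAccuracy:
    def test_pooled_ai_counts(self):
        m = make_matrix(
            {"chatgpt": [1] * 4 + [0] * 21,
             "grok": [1] * 4 + [0] * 21,
             "gemini": [1] * 8 + [0] * 16 + [None],
             "claude": [1] * 2 + [0] * 23},
            {r: r for r in ("chatgpt", "grok", "gemini", "claude")})
        res = accuracy(m, groups=["chatgpt", "grok", "gemini", "claude"])
        assert (res.k, res.n) == (18, 99)
        assert res.proportion == pytest.approx(18 / 99)

    def test_all_ones(self):
        m = make_matrix({"a": [1, 1], "b": [1, 1]}, {"a": "g", "b": "g"})
        res = accuracy(m)
        assert res.proportion == 1.0 and res.ci_upper == 1.0

    def test_missing_cells_excluded_from_denominator(self):
        m = make_matrix({"a": [1, 0, None]}, {"a": "g"})
        res = accuracy(m, rater="a")
        assert res.n == 2

    def test_empty_selection_rejected(self):
        m = make_matrix({"a": [None, None]}, {"a": "g"})
        with pytest.raises(ValueError, match="no evaluations"):
            accuracy(m)


class TestPearsonChi2:
    def test_ai_sd_dd_table(self):
        # per-model SD+DD correct/incorrect: the between-model difference
        # is significant at ~0.04
        stat, df, p = pearson_chi2([[13, 12], [10, 15], [15, 9], [6, 19]])
        assert df == 3
        assert 0.035 < p < 0.045

    def test_identical_rows_give_zero_statistic(self):
        stat, df, p = pearson_chi2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_two_equals_squared_z_statistic(self):
        k1, n1, k2, n2 = 30, 80, 18, 60
        stat, _, _ = pearson_chi2([[k1, n1 - k1], [k2, n2 - k2]])
        p1, p2 = k1 / n1, k2 / n2
        pool = (k1 + k2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(z**2, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            pearson_chi2([[0, 5], [0, 7]])


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by explicit enumeration over the fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = sps.hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ([[3, 1], [1, 3]], 34 / 70),       # enumeration over 5 tables
        ([[0, 5], [5, 0]], 2 / 252),
    ])
    def test_hand_enumerated_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-9)

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, (2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_exact_2x2(t.T), rel=1e-9)

    def test_monte_carlo_agrees_with_exact_on_2x2(self):
        table = [[3, 7], [8, 2]]
        exact = fisher_exact_2x2(table)
        mc = fisher_monte_carlo(table, n_samples=50_000, seed=12)
        assert mc == pytest.approx(exact, abs=0.01)


class TestHolm:
    def test_stepdown_example(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == [0.2]

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_adjusted_at_least_raw_and_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.random(rng.integers(1, 8))
            adj = np.asarray(holm_adjust(p))
            assert (adj >= p - 1e-15).all() and (adj <= 1).all()
            _, sm_adj, _, _ = multipletests(p, method="holm")
            assert adj == pytest.approx(sm_adj, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestCompareGroups:
    def two_group_matrix(self, k1, n1, k2, n2):
        return make_matrix(
            {"a": [1] * k1 + [0] * (n1 - k1), "b": [1] * k2 + [0] * (n2 - k2)},
            {"a": "g1", "b": "g2"})

    def test_identical_groups_not_significant(self):
        res = compare_groups(self.two_group_matrix(10, 20, 10, 20))
        assert res.p_value == pytest.approx(1.0)
        assert res.pairwise == ()

    def test_posthoc_adjusted_at_least_raw(self):
        m = make_matrix(
            {"a": [1] * 18 + [0] * 2, "b": [1] * 10 + [0] * 10,
             "c": [1] * 3 + [0] * 17},
            {"a": "g1", "b": "g2", "c": "g3"})
        res = compare_groups(m)
        assert res.p_value < 0.05 and len(res.pairwise) == 3
        for pw in res.pairwise:
            assert pw.p_adjusted >= pw.p_raw - 1e-15

    def test_small_counts_switch_to_fisher(self):
        res = compare_groups(self.two_group_matrix(1, 6, 5, 6))
        assert res.test == "fisher"

    def test_grouping_pools_groups(self):
        m = make_matrix(
            {"a": [1, 1, 0, 0], "b": [1, 0, 0, 0], "c": [1, 1, 1, 0]},
            {"a": "g1", "b": "g2", "c": "g3"})
        res = compare_groups(m, grouping={"g1": "x", "g2": "x", "g3": "y"})
        assert set(res.groups) == {"x", "y"}
        assert dict(zip(res.groups, res.table))["x"] == (3, 5)

    def test_empty_group_rejected(self):
        m = make_matrix({"a": [1, 0], "b": [None, None]},
                        {"a": "g1", "b": "g2"})
        with pytest.raises(ValueError, match="no evaluations"):
            compare_groups(m)
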