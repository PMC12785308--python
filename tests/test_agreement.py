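"""Gwet's AC1: worked examples, invariances, jackknife behaviour."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from trichostudy.agreement import (between_group_agreement, categorize_ac1,
                                   gwet_ac1, majority_vote)
from trichostudy.scoring import CorrectnessMatrix


def ac1_full_matrix_formula(values: np.ndarray):
    """Independent vectorised route: full-matrix AC1 for the dual-route check."""
    present = np.isfinite(values)
    r = present.sum(axis=0)
    keep = r >= 2
    r = r[keep].astype(float)
    ones = np.nansum(values[:, keep], axis=0)
    p_a = ((ones * (ones - 1) + (r - ones) * (r - ones - 1)) / (r * (r - 1))).mean()
    pi = (ones / r).mean()
    p_e = 2 * pi * (1 - pi)
    return (p_a - p_e) / (1 - p_e)


def random_matrix(rng, n_raters=6, n_items=15, p_missing=0.1):
    vals = (rng.random((n_raters, n_items)) < rng.random(n_items)).astype(float)
    vals[rng.random((n_raters, n_items)) < p_missing] = np.nan
    df = pd.DataFrame(vals, index=[f"r{i}" for i in range(n_raters)],
                      columns=[f"c{j}" for j in range(n_items)])
    return CorrectnessMatrix(df, pd.Series({f"r{i}": "g" for i in range(n_raters)}))


class TestGwetAC1:
    def test_perfect_agreement(self):
        m = make_matrix({"a": [1, 0, 1, 0], "b": [1, 0, 1, 0], "c": [1, 0, 1, 0]},
                        {k: "g" for k in "abc"})
        res = gwet_ac1(m)
        assert res.observed_agreement == 1.0
        assert res.ac1 == pytest.approx(1.0)
        assert res.category == "very good"

    def test_two_rater_worked_example(self):
        # ratings (1,1,0,0) vs (1,0,0,0): p_a = 3/4, pi = 3/8,
        # p_e = 2 * 3/8 * 5/8 = 15/32, AC1 = (3/4 - 15/32)/(1 - 15/32)
        m = make_matrix({"a": [1, 1, 0, 0], "b": [1, 0, 0, 0]},
                        {"a": "g", "b": "g"})
        res = gwet_ac1(m)
        assert res.observed_agreement == pytest.approx(0.75)
        assert res.prevalence == pytest.approx(0.375)
        assert res.chance_agreement == pytest.approx(0.46875)
        assert res.ac1 == pytest.approx(0.529412, abs=1e-6)

    def test_singleton_item_excluded(self):
        base = make_matrix({"a": [1, 1, 0, 0], "b": [1, 0, 0, 0]},
                           {"a": "g", "b": "g"})
        extra = make_matrix({"a": [1, 1, 0, 0, 1], "b": [1, 0, 0, 0, None]},
                            {"a": "g", "b": "g"})
        assert gwet_ac1(extra).ac1 == pytest.approx(gwet_ac1(base).ac1)
        assert gwet_ac1(extra).n_items == 4

    def test_dual_route_identity(self, rng):
        # streaming implementation vs independent full-matrix formula
        for _ in range(25):
            m = random_matrix(rng)
            expected = ac1_full_matrix_formula(m.values.to_numpy())
            assert gwet_ac1(m).ac1 == pytest.approx(expected, abs=1e-12)

    def test_closed_form_at_half_prevalence(self):
        # 2 raters, prevalence exactly 0.5: AC1 = (p_a - 0.5) / 0.5
        m = make_matrix({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]},
                        {"a": "g", "b": "g"})
        res = gwet_ac1(m)
        assert res.prevalence == pytest.approx(0.5)
        assert res.ac1 == pytest.approx((res.observed_agreement - 0.5) / 0.5)

    def test_label_swap_invariance(self, rng):
        for _ in range(10):
            m = random_matrix(rng)
            swapped = CorrectnessMatrix(1.0 - m.values, m.groups)
            assert gwet_ac1(swapped).ac1 == pytest.approx(gwet_ac1(m).ac1,
                                                          abs=1e-12)

    def test_jackknife_se_shrinks_on_duplicated_items(self, rng):
        m = random_matrix(rng, n_raters=5, n_items=20, p_missing=0.0)
        doubled = CorrectnessMatrix(
            pd.concat([m.values, m.values.add_suffix("_dup")], axis=1),
            m.groups)
        se1 = gwet_ac1(m).se
        se2 = gwet_ac1(doubled).se
        assert se2 == pytest.approx(se1 / np.sqrt(2), rel=0.10)

    def test_validation(self):
        with pytest.raises(ValueError, match="2 raters"):
            gwet_ac1(make_matrix({"a": [1, 0]}, {"a": "g"}))
        with pytest.raises(ValueError, match="2 items"):
            gwet_ac1(make_matrix({"a": [1, None], "b": [1, None]},
                                 {"a": "g", "b": "g"}))

    def test_ci_truncated_and_ordered(self, rng):
        for _ in range(10):
            res = gwet_ac1(random_matrix(rng, n_items=6))
            assert -1 <= res.ci_lower <= res.ac1 <= res.ci_upper <= 1


class TestCategorize:
    @pytest.mark.parametrize("value,label", [
        (-0.1, "poor"), (0.0, "slight"), (0.10, "slight"), (0.20, "slight"),
        (0.21, "fair"), (0.40, "fair"), (0.41, "moderate"), (0.60, "moderate"),
        (0.61, "good"), (0.70, "good"), (0.80, "good"), (0.81, "very good"),
        (1.0, "very good"),
    ])
    def test_bands(self, value, label):
        assert categorize_ac1(value) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            categorize_ac1(1.2)


class TestBetweenGroups:
    def test_unanimous_identical_groups(self):
        m = make_matrix(
            {"a1": [1, 0, 1], "a2": [1, 0, 1], "b1": [1, 0, 1], "b2": [1, 0, 1]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = between_group_agreement(m)
        assert res.ac1 == pytest.approx(1.0)
        assert res.n_raters == 2  # two pseudo-raters

    def test_opposite_groups_have_zero_observed_agreement(self):
        m = make_matrix({"a1": [1, 1, 1], "b1": [0, 0, 0]},
                        {"a1": "A", "b1": "B"})
        res = between_group_agreement(m)
        assert res.observed_agreement == 0.0

    def test_ties_count_as_incorrect(self):
        m = make_matrix({"a1": [1, 1], "a2": [0, 1]}, {"a1": "A", "a2": "A"})
        votes = majority_vote(m, ["a1", "a2"])
        assert votes.tolist() == [0.0, 1.0]

    def test_equals_ac1_on_majority_vectors(self, rng):
        # construction identity: 3 pseudo-raters == AC1 of the 3 vote vectors
        m = random_matrix(rng, n_raters=9, n_items=20, p_missing=0.0)
        groups = pd.Series({f"r{i}": f"G{i % 3}" for i in range(9)})
        m = CorrectnessMatrix(m.values, groups)
        res = between_group_agreement(m)
        votes = pd.DataFrame({g: majority_vote(m, m.raters_in(g))
                              for g in ("G0", "G1", "G2")}).T
        direct = gwet_ac1(CorrectnessMatrix(
            votes, pd.Series({g: g for g in ("G0", "G1", "G2")})))
        assert res.ac1 == pytest.approx(direct.ac1, abs=1e-12)
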