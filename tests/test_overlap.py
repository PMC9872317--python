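"""Hypergeometric overlap statistics, movement patterns, Welch t."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
import pandas as pd

from spermre.overlap import (
    DBPComparison,
    classify_movement,
    consistent_responders,
    hypergeometric_overlap,
    intersect_lists,
    movement_table,
    shared_between_arms,
    welch_t,
)


def brute_force_tails(x, n1, n2, N):
    """Exact tail sums by integer enumeration (independent of scipy)."""
    total = math.comb(N, n2)
    lo, hi = max(0, n1 + n2 - N), min(n1, n2)
    over = sum(math.comb(n1, k) * math.comb(N - n1, n2 - k) for k in range(x, hi + 1))
    under = sum(math.comb(n1, k) * math.comb(N - n1, n2 - k) for k in range(lo, x + 1))
    return over / total, under / total


class TestHypergeometricOverlap:
    def test_derived_example_against_enumeration(self):
        res = hypergeometric_overlap(10, 20, 30, 100)
        assert res.expected == pytest.approx(6.0)
        assert res.representation_factor == pytest.approx(10 / 6, abs=1e-4)
        over, under = brute_force_tails(10, 20, 30, 100)
        assert res.p_over == pytest.approx(over, rel=1e-10)
        assert res.p_under == pytest.approx(under, rel=1e-10)

    def test_at_expectation(self):
        res = hypergeometric_overlap(1, 10, 10, 100)
        assert res.expected == pytest.approx(1.0)
        assert res.representation_factor == pytest.approx(1.0)

    def test_certain_overlap(self):
        res = hypergeometric_overlap(7, 7, 50, 50)
        assert res.representation_factor == pytest.approx(1.0)
        assert res.p_over == pytest.approx(1.0)

    def test_infeasible_x_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(11, 10, 10, 100)
        with pytest.raises(ValueError):
            hypergeometric_overlap(0, 60, 60, 100)  # lower bound is 20
        with pytest.raises(ValueError):
            hypergeometric_overlap(0, 0, 0, 0)

    def test_rf_times_expected_is_x(self):
        for x, n1, n2, N in [(3, 9, 4, 40), (0, 5, 5, 50), (12, 20, 30, 60)]:
            res = hypergeometric_overlap(x, n1, n2, N)
            assert res.representation_factor * res.expected == pytest.approx(x)

    def test_p_over_nonincreasing_in_x(self):
        ps = [hypergeometric_overlap(x, 20, 30, 100).p_over for x in range(0, 21)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    @given(
        N=st.integers(min_value=1, max_value=50),
        data=st.data(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_oracle_equivalence_random(self, N, data):
        n1 = data.draw(st.integers(0, N))
        n2 = data.draw(st.integers(0, N))
        lo, hi = max(0, n1 + n2 - N), min(n1, n2)
        x = data.draw(st.integers(lo, hi))
        res = hypergeometric_overlap(x, n1, n2, N)
        over, under = brute_force_tails(x, n1, n2, N)
        assert res.p_over == pytest.approx(over, rel=1e-9, abs=1e-12)
        assert res.p_under == pytest.approx(under, rel=1e-9, abs=1e-12)

    def test_normal_approximation_close_at_large_N(self):
        N = 5000
        n1, n2 = 500, 800
        for x in (50, 80, 100, 120):
            exact = hypergeometric_overlap(x, n1, n2, N, method="exact")
            approx = hypergeometric_overlap(x, n1, n2, N, method="normal_approx")
            assert approx.p_over == pytest.approx(exact.p_over, abs=0.01)
            assert approx.p_under == pytest.approx(exact.p_under, abs=0.01)


def test_intersect_lists_normalizes_case():
    assert intersect_lists(["Cul2", "B", "C"], ["CUL2", "c", "D"]) == ["C", "CUL2"]
    assert intersect_lists(["A"], ["B"]) == []


class TestMovement:
    def test_down_then_stable(self):
        mp = classify_movement(45.88953277, 36.94494826, 33.3796977, True, False)
        assert mp.label == "Down—same"

    def test_up_both_segments(self):
        mp = classify_movement(10.9300058, 12.60999224, 16.5514561, True, True)
        assert mp.label == "Up—up"

    def test_no_significance_means_same(self):
        assert classify_movement(5, 5, 5, False, False).label == "Same—same"

    def test_equal_means_with_significance_errors(self):
        with pytest.raises(ValueError):
            classify_movement(5, 5, 9, True, False)

    @given(
        base=st.floats(min_value=0, max_value=100),
        d1=st.floats(min_value=-50, max_value=50),
        d2=st.floats(min_value=-50, max_value=50),
        shift=st.floats(min_value=0, max_value=1000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_shift_invariance(self, base, d1, d2, shift):
        a, b, c = base, base + d1, base + d1 + d2
        if min(a, b, c) < 0 or b == a or c == b:
            return
        if (a + shift == b + shift) or (b + shift == c + shift):
            return
        m1 = classify_movement(a, b, c, True, True)
        m2 = classify_movement(a + shift, b + shift, c + shift, True, True)
        assert m1.label == m2.label


def test_movement_table_uses_membership_flags():
    vm = pd.DataFrame(
        {"baseline": [10.0, 10.0], "crossover": [20.0, 20.0],
         "crossback": [5.0, 5.0]},
        index=pd.Index(["r1", "r2"], name="re_id"),
    )
    mt = movement_table(vm, sig_first={"r1"}, sig_second={"r1", "r2"})
    assert mt.loc["r1", "pattern"] == "Up—down"
    assert mt.loc["r2", "pattern"] == "Same—down"


class TestConsistentResponders:
    def moves(self, rows):
        return pd.DataFrame(rows, columns=["gene", "segment", "direction"])

    def test_coherent_gene_included(self):
        m = self.moves([("G1", "B1H", "up"), ("G1", "BH2", "up"),
                        ("G1", "H1B", "down")])
        assert consistent_responders(m) == ["G1"]

    def test_same_direction_on_addition_and_withdrawal_excluded(self):
        m = self.moves([("G1", "B1H", "up"), ("G1", "H1B", "up")])
        assert consistent_responders(m) == []

    def test_single_comparison_excluded(self):
        m = self.moves([("G1", "B1H", "up")])
        assert consistent_responders(m) == []

    def test_internal_contradiction_excluded(self):
        m = self.moves([("G1", "B1H", "up"), ("G1", "BH2", "down"),
                        ("G1", "H1B", "down")])
        assert consistent_responders(m) == []


def test_shared_between_arms():
    a, b, shared = shared_between_arms(["A", "B"], ["B", "C"])
    assert (a, b, shared) == (["A"], ["C"], ["B"])
    a, b, shared = shared_between_arms(["X"], ["X"])
    assert (a, b, shared) == ([], [], ["X"])
    a, b, shared = shared_between_arms(["X"], ["Y"])
    assert shared == []


class TestWelch:
    def test_identical_vectors(self):
        t, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        from scipy import stats

        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        # independent hand computation of the Welch statistic and df
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        se2 = vx / len(x) + vy / len(y)
        t_hand = (np.mean(x) - np.mean(y)) / math.sqrt(se2)
        df_hand = se2**2 / (
            (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
        )
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        t, p = welch_t(x, y)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_p_shrinks_with_shift(self):
        x = [1.0, 2.0, 3.0, 4.0]
        ps = [welch_t([v + shift for v in x], x)[1] for shift in (1, 5, 50)]
        assert ps[0] > ps[1] > ps[2]

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def test_dbp_comparison_validation():
    entries = pd.DataFrame(
        {"re_id": ["r"], "gene": ["G"], "direction": ["up"], "empirical_p": [0.01]}
    )
    DBPComparison(arm="B1HB2", segment="B1H", entries=entries)
    with pytest.raises(ValueError):
        DBPComparison(arm="H1BH2", segment="B1H", entries=entries)
    bad = entries.assign(empirical_p=[0.2])
    with pytest.raises(ValueError):
        DBPComparison(arm="B1HB2", segment="B1H", entries=bad)
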