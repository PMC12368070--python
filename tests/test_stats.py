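from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from polvel.stats import (bh_adjust, boxplot_summary, ma_table,
                          wilcoxon_rank_sum, wilcoxon_signed_rank)


def enumerate_signed_rank_p(values):
    """Independent oracle: exhaustive enumeration over all sign assignments
    of |values| with midranks."""
    d = np.asarray(values, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in product([False, True], repeat=len(d))]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def enumerate_rank_sum_p(a, b):
    """Oracle: all C(n1+n2, n1) assignments of the pooled ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    ws = np.array([sum(ranks[list(idx)]) for idx in
                   combinations(range(len(pooled)), n1)])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestSignedRank:
    def test_all_positive_small_sample(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.method == "signed_rank_exact"
        assert res.p_value == pytest.approx(0.03125)

    def test_symmetric_pair_gives_p_one(self):
        assert wilcoxon_signed_rank([-1, 1]).p_value == pytest.approx(1.0)

    def test_all_zeros_rejected(self):
        with pytest.raises(ValueError, match="equal mu"):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_mu_shift(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6, 7], mu=1.0)
        assert res.p_value == pytest.approx(0.03125)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_exact_p_matches_enumeration_all_sign_patterns(self, n):
        """Exhaustive: every sign pattern of magnitudes 1..n (with one tie
        pair when n >= 4) agrees with the 2^n enumeration oracle."""
        mags = np.arange(1, n + 1, dtype=float)
        if n >= 4:
            mags[1] = mags[2]  # inject a tie in |d|
        for signs in product([-1.0, 1.0], repeat=n):
            vals = mags * np.array(signs)
            ours = wilcoxon_signed_rank(vals)
            assert ours.method == "signed_rank_exact"
            assert ours.p_value == pytest.approx(enumerate_signed_rank_p(vals))

    def test_exact_and_normal_agree_at_boundary(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.3, 1.0, 25)
        exact = wilcoxon_signed_rank(x)
        # force the approximation path on the same data
        import polvel.stats as ps
        orig = ps.EXACT_LIMIT_SIGNED
        try:
            ps.EXACT_LIMIT_SIGNED = 0
            approx = wilcoxon_signed_rank(x)
        finally:
            ps.EXACT_LIMIT_SIGNED = orig
        assert approx.method == "signed_rank_normal"
        assert abs(exact.p_value - approx.p_value) < 0.01

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.5, 1.0, 15)
        ours = wilcoxon_signed_rank(x)
        ref = sps.wilcoxon(x, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50).filter(lambda v: v != 0),
                    min_size=2, max_size=8))
    def test_property_exact_equals_enumeration(self, vals):
        ours = wilcoxon_signed_rank(np.array(vals, dtype=float))
        assert ours.p_value == pytest.approx(enumerate_signed_rank_p(vals))

    def test_null_p_super_uniform(self):
        rng = np.random.default_rng(12)
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(0, 1, 12)
            if wilcoxon_signed_rank(x).p_value <= 0.05:
                hits += 1
        assert hits / n_sim <= 0.06


class TestRankSum:
    def test_two_two_exact(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "rank_sum_exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [3, 1, 2]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 3)])
    def test_exact_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        a = rng.normal(0, 1, n1)
        b = rng.normal(1, 1, n2)
        ours = wilcoxon_rank_sum(a, b)
        assert ours.p_value == pytest.approx(enumerate_rank_sum_p(a, b))

    def test_ties_handled_exactly(self):
        a, b = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        assert wilcoxon_rank_sum(a, b).p_value == pytest.approx(
            enumerate_rank_sum_p(a, b))

    def test_p_decreases_with_location_shift(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 40)
        other = rng.normal(0, 1, 40)
        ps_ = [wilcoxon_rank_sum(base, other + shift).p_value
               for shift in (0.0, 0.5, 1.0, 2.0)]
        assert all(ps_[i] >= ps_[i + 1] for i in range(len(ps_) - 1))

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 35)
        ours = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestBH:
    def test_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_monotone(self, ps_):
        adj = bh_adjust(ps_)
        assert np.all(adj >= np.asarray(ps_) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps_)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_flat_adjusted_vectors_are_fixed_points(self):
        # the monotone cap makes any all-equal vector (e.g. the output of
        # adjusting (0.01, 0.02, 0.03)) a fixed point of re-adjustment
        adj = bh_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(bh_adjust(adj), adj)
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)


class TestBoxplot:
    def test_one_to_nine_hand_computation(self):
        s = boxplot_summary(range(1, 10))
        assert s.median == 5 and s.hinge_lo == 3 and s.hinge_hi == 7
        assert s.notch_lo == pytest.approx(2.8933, abs=1e-4)
        assert s.notch_hi == pytest.approx(7.1067, abs=1e-4)
        assert s.whisker_lo == 1 and s.whisker_hi == 9

    def test_constant_data(self):
        s = boxplot_summary([4.0] * 6)
        assert s.median == s.hinge_lo == s.hinge_hi == 4.0
        assert s.notch_lo == s.notch_hi == 4.0

    def test_single_value(self):
        s = boxplot_summary([2.5])
        assert s.hinge_lo == s.hinge_hi == s.median == 2.5
        assert s.whisker_lo == s.whisker_hi == 2.5

    def test_whiskers_are_attained_values_within_fence(self):
        vals = [1, 2, 3, 4, 5, 100]  # 100 is an outlier
        s = boxplot_summary(vals)
        assert s.whisker_hi == 5
        assert s.whisker_lo == 1


class TestMATable:
    import pandas as pd

    def test_log2_fc_with_pseudo_count(self):
        import pandas as pd
        counts = pd.DataFrame({"c1": [15], "c2": [15], "t1": [7], "t2": [7]},
                              index=["g"])
        sf = pd.Series(1.0, index=counts.columns)
        ma = ma_table(counts, sf, ["c1", "c2"], ["t1", "t2"])
        assert ma.loc["g", "log2_fc"] == pytest.approx(np.log2(8 / 16))

    def test_equal_means_give_zero(self):
        import pandas as pd
        counts = pd.DataFrame({"c1": [9], "t1": [9]}, index=["g"])
        sf = pd.Series(1.0, index=counts.columns)
        assert ma_table(counts, sf, ["c1"], ["t1"]).loc["g", "log2_fc"] == 0

    def test_size_factor_applied_before_averaging(self):
        import pandas as pd
        counts = pd.DataFrame({"c1": [30], "t1": [30]}, index=["g"])
        sf = pd.Series({"c1": 1.0, "t1": 2.0})
        ma = ma_table(counts, sf, ["c1"], ["t1"])
        assert ma.loc["g", "mean_treated"] == pytest.approx(15.0)
        assert ma.loc["g", "log2_fc"] == pytest.approx(np.log2(16 / 31))
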