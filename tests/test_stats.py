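"""Survival / hypothesis-testing primitives against closed forms and
brute-force enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations, product
from scipy.stats import hypergeom

from ecsurv.stats import (
    NOT_REACHED,
    bh_fdr,
    fisher_exact,
    kaplan_meier,
    logrank_test,
    nelson_aalen,
    pairwise_logrank_matrix,
    reverse_km_median_followup,
    two_sample_logrank,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = kaplan_meier([1, 2, 3], [True, True, True])
        assert km(1) == pytest.approx(2 / 3)
        assert km(2) == pytest.approx(1 / 3)
        assert km(3) == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        km = kaplan_meier([5, 10, 20], [False, False, False])
        assert np.all(km([1, 10, 30]) == 1.0)

    def test_censoring_product_limit_oracle(self):
        # hand product-limit: S(1) = 2/3, censor at 2 removes one at risk,
        # S(3) = 2/3 * (1 - 1/1) = 0
        km = kaplan_meier([1, 2, 3], [True, False, True])
        assert km(1) == pytest.approx(2 / 3)
        assert km(3) == pytest.approx(0.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestNelsonAalen:
    def test_closed_form(self):
        na = nelson_aalen([1, 2], [True, True])
        assert na(2) == pytest.approx(0.5 + 1.0)

    def test_all_censored_zero(self):
        na = nelson_aalen([1, 2, 3], [False] * 3)
        assert np.all(na([1, 2, 3]) == 0.0)

    def test_exp_minus_na_close_to_km(self, rng):
        # first-order equivalence of the two estimators on a decent sample
        t = rng.exponential(20, 200)
        e = rng.random(200) < 0.7
        km = kaplan_meier(t, e)
        na = nelson_aalen(t, e)
        grid = np.linspace(0.5, np.quantile(t, 0.95), 100)
        assert np.max(np.abs(np.exp(-na(grid)) - km(grid))) < 0.05


class TestReverseKM:
    def test_point_mass_censoring(self):
        assert reverse_km_median_followup([60] * 5, [False] * 5) == 60

    def test_all_events_not_reached(self):
        assert reverse_km_median_followup([1, 2, 3], [True] * 3) == NOT_REACHED

    def test_equals_km_on_swapped_indicators(self):
        times = [3, 5, 8, 12, 14, 20, 30, 40, 55, 60]
        events = [True, False, True, False, False, True, False, True, False, False]
        med = reverse_km_median_followup(times, events)
        km = kaplan_meier(times, [not e for e in events])
        # smallest observed time with S <= 0.5
        candidates = [t for t in times if km(t) <= 0.5]
        assert med == pytest.approx(min(candidates))


class TestLogrank:
    def test_identical_groups_degenerate(self):
        sample = ([1, 2, 3, 4], [True, True, False, True])
        stat, p = logrank_test([sample, sample])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_separated_groups(self):
        stat, p = logrank_test([([1, 2], [True, True]), ([10, 20], [True, True])])
        assert stat > 0
        assert p < 0.2

    def test_three_identical_groups(self):
        s = ([1, 2, 3], [True, True, True])
        stat, _ = logrank_test([s, s, s])
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_relabeling_invariance(self, rng):
        a = (rng.exponential(10, 40), rng.random(40) < 0.8)
        b = (rng.exponential(20, 50), rng.random(50) < 0.8)
        stat_ab, p_ab = logrank_test([a, b])
        stat_ba, p_ba = logrank_test([b, a])
        assert stat_ab == pytest.approx(stat_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_fast_two_sample_matches_lifelines(self, rng):
        t = np.concatenate([rng.exponential(30, 80), rng.exponential(15, 90)])
        e = rng.random(170) < 0.8
        mask = np.zeros(170, bool)
        mask[:80] = True
        stat_fast, p_fast = two_sample_logrank(t, e, mask)
        stat_ll, p_ll = logrank_test([(t[mask], e[mask]), (t[~mask], e[~mask])])
        assert stat_fast == pytest.approx(stat_ll, rel=1e-9)
        assert p_fast == pytest.approx(p_ll, rel=1e-6)


def _signed_rank_oracle(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=len(d))]
    )
    return min(2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()), 1.0)


def _rank_sum_oracle(a, b):
    na = len(a)
    ranks = np.argsort(np.argsort(np.concatenate([a, b]))) + 1
    r_obs = ranks[:na].sum()
    rs = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(len(ranks)), na)]
    )
    return min(2 * min((rs <= r_obs).mean(), (rs >= r_obs).mean()), 1.0)


def _fisher_oracle(table):
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return min(
        sum(
            hypergeom.pmf(x, n, r1, c1)
            for x in range(max(0, c1 - (c + d)), min(r1, c1) + 1)
            if hypergeom.pmf(x, n, r1, c1) <= p_obs * (1 + 1e-7)
        ),
        1.0,
    )


class TestWilcoxonSignedRank:
    def test_identical_pairs_degenerate(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_sign_flip_enumeration(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(0, 1, 9), r.normal(0.4, 1, 9)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(_signed_rank_oracle(a, b))

    def test_large_uniform_shift(self):
        b = np.arange(20, dtype=float)
        assert wilcoxon_signed_rank(b + 5.0, b) < 0.001


class TestWilcoxonRankSum:
    def test_same_multiset(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rank_assignment_enumeration(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(0, 1, 5), r.normal(0.8, 1, 6)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(_rank_sum_oracle(a, b))

    def test_disjoint_ranges(self):
        assert wilcoxon_rank_sum(np.arange(10.0), np.arange(100.0, 110.0)) < 0.001


class TestFisherExact:
    def test_identical_rows_independent(self):
        assert fisher_exact([[5, 7], [5, 7]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [[[3, 7], [6, 4]], [[1, 9], [8, 2]], [[5, 5], [5, 5]], [[2, 11], [1, 6]]]
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert fisher_exact(table) == pytest.approx(_fisher_oracle(table))

    def test_perfect_association(self):
        assert fisher_exact([[10, 0], [0, 10]]) < 0.001

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0


class TestBHFDR:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_equal_values_unchanged(self):
        assert bh_fdr([0.031])[0] == pytest.approx(0.031)
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_never_below_raw(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)

    def test_order_preserved(self):
        p = [0.04, 0.001, 0.5]
        adj = bh_fdr(p)
        # adjusted value of the smallest raw p stays the smallest
        assert np.argmin(adj) == np.argmin(p)


def test_pairwise_matrix_shape(rng):
    groups = [(rng.exponential(s, 30), rng.random(30) < 0.8) for s in (5, 10, 30)]
    pairs, p_raw, p_adj = pairwise_logrank_matrix(groups)
    assert pairs == [(0, 1), (0, 2), (1, 2)]
    assert np.all((p_raw >= 0) & (p_raw <= 1))
    assert np.all(p_adj >= p_raw - 1e-12)
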