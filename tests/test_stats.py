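"""Rank tests against exhaustive enumeration, Holm correction, permutation."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from eegduo import EpochSet
from eegduo.stats import (
    holm_bonferroni,
    mann_whitney_u,
    permutation_condition_test,
    wilcoxon_signed_rank,
    window_roi_amplitudes,
)

FS = 128.0


def exact_wilcoxon_p(d):
    """Two-sided signed-rank p by enumerating every sign assignment."""
    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    w_all = np.array([np.sum(ranks[list(signs)])
                      for signs in (np.array(s, dtype=bool)
                                    for s in itertools.product([0, 1],
                                                               repeat=n))])
    p_low = np.mean(w_all <= w_obs)
    p_high = np.mean(w_all >= w_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def exact_mannwhitney_p(a, b):
    """Two-sided U-test p by enumerating every group labelling."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        us.append(ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0)
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestWilcoxon:
    def test_identical_samples_degenerate_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert "degenerate" in res.method

    def test_large_shift_gives_minimal_attainable_p(self):
        # distinct positive differences -> exact method; all signs agree
        n = 8
        b = np.arange(n, dtype=float)
        a = b + 100.0 + 0.01 * np.arange(n)
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(2.0 / 2 ** n)
        assert res.statistic > 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration_n6(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.4, 1.0, 6)
        b = rng.normal(0.0, 1.0, 6)
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(exact_wilcoxon_p(a - b), abs=1e-12)

    def test_too_few_nonzero_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 3.0], [1.0, 2.0, 3.0, 2.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestMannWhitney:
    def test_fully_separated_samples_give_extreme_u(self):
        res = mann_whitney_u([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert res.statistic in (0.0, 9.0)
        res2 = mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res2.statistic in (0.0, 9.0)

    def test_balanced_identical_distributions_centre_u(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=50), rng.normal(size=50)
        res = mann_whitney_u(a, b)
        assert abs(res.statistic - 50 * 50 / 2) < 50 * 50 / 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration_4v4(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.8, 1.0, 4)
        b = rng.normal(0.0, 1.0, 4)
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(exact_mannwhitney_p(a, b),
                                            abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestHolm:
    def test_single_p_reduces_to_plain_test(self):
        res = holm_bonferroni([0.04], alpha=0.05)
        assert res.reject.tolist() == [True]

    def test_hand_stepped_examples(self):
        # sorted p: 0.01 <= .05/3 -> reject; 0.03 > .05/2 -> stop there
        res = holm_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        assert res.reject.tolist() == [True, False, False]
        # 0.01 <= .05/3, 0.02 <= .05/2, 0.04 <= .05/1: all rejected
        res2 = holm_bonferroni([0.01, 0.04, 0.02], alpha=0.05)
        assert res2.reject.tolist() == [True, True, True]

    def test_step_down_stops_at_first_failure(self):
        res = holm_bonferroni([0.01, 0.03, 0.04], alpha=0.06)
        assert res.reject.tolist() == [True, True, True]
        res2 = holm_bonferroni([0.03, 0.2, 0.8], alpha=0.05)
        assert res2.reject.tolist() == [False, False, False]

    def test_all_ones_give_no_rejections(self):
        res = holm_bonferroni([1.0, 1.0, 1.0])
        assert not res.reject.any()
        assert np.allclose(res.adjusted_p, 1.0)

    def test_adjusted_p_monotone_and_capped(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 10)
        res = holm_bonferroni(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.adjusted_p[order]) >= -1e-12)
        assert res.adjusted_p.max() <= 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.1, 1.4])


def make_epochs(values, labels):
    """One-channel epochs whose window mean equals each trial value."""
    values = np.asarray(values, dtype=float)
    data = np.tile(values[:, None, None], (1, 1, 128))
    return EpochSet(data, FS, ("C0",), (-200.0, 800.0),
                    np.array(labels, dtype=object),
                    np.ones(len(values), dtype=bool))


class TestPermutationTest:
    def test_window_roi_amplitude_extraction(self):
        ep = make_epochs([1.0, 2.0, 5.0], ["a", "a", "b"])
        amps = window_roi_amplitudes(ep, (200.0, 300.0), ("C0",))
        assert np.allclose(amps, [1.0, 2.0, 5.0])

    def test_matches_exhaustive_enumeration_on_tiny_input(self):
        values = np.array([3.1, 2.9, 3.4, 1.0, 0.8, 1.3])
        labels = ["a"] * 3 + ["b"] * 3
        ep = make_epochs(values, labels)
        obs = values[:3].mean() - values[3:].mean()
        null = [values[list(c)].mean()
                - values[[i for i in range(6) if i not in c]].mean()
                for c in itertools.combinations(range(6), 3)]
        exact_p = np.mean(np.abs(null) >= abs(obs) - 1e-12)
        res = permutation_condition_test(ep, (0.0, 400.0), ("C0",),
                                         conditions=("a", "b"), n_perm=1000,
                                         seed=0)
        assert abs(res.p_value - exact_p) < 4.0 / np.sqrt(1000)

    def test_p_invariant_to_adding_constant(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 30)
        labels = ["a"] * 20 + ["b"] * 10
        p1 = permutation_condition_test(make_epochs(values, labels),
                                        (0.0, 400.0), ("C0",), n_perm=500,
                                        seed=9).p_value
        p2 = permutation_condition_test(make_epochs(values + 42.0, labels),
                                        (0.0, 400.0), ("C0",), n_perm=500,
                                        seed=9).p_value
        assert p1 == p2

    def test_deterministic_for_fixed_seed_and_add_one_floor(self):
        values = np.concatenate([np.full(10, 5.0), np.zeros(10)])
        labels = ["a"] * 10 + ["b"] * 10
        ep = make_epochs(values, labels)
        r1 = permutation_condition_test(ep, (0.0, 400.0), ("C0",), n_perm=200,
                                        seed=4)
        r2 = permutation_condition_test(ep, (0.0, 400.0), ("C0",), n_perm=200,
                                        seed=4)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1.0 / 201.0

    def test_single_condition_rejected(self):
        ep = make_epochs([1.0, 2.0], ["a", "a"])
        with pytest.raises(ValueError):
            permutation_condition_test(ep, (0.0, 400.0), ("C0",))

    def test_default_condition_order_is_nogo_minus_go(self):
        values = np.array([1.0, 1.0, 4.0, 4.0])
        ep = make_epochs(values, ["Go", "Go", "NoGo", "NoGo"])
        res = permutation_condition_test(ep, (0.0, 400.0), ("C0",),
                                         n_perm=100, seed=0)
        assert res.observed == pytest.approx(3.0)
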