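"""Filter statistics against hand evaluations and a brute-force oracle.

The oracle recomputes W, kappa, tau, the adaptive threshold, and the
selected set with plain Python loops straight from the definitions, fully
independently of the vectorized implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest

from knockoffml.attribution import ImportanceVector
from knockoffml.knockoff_filter import (
    adaptive_threshold,
    compute_stats,
    consensus,
    kappa_tau,
    knockoff_statistic,
    q_values,
    rank_features,
    select,
)


def make_iv(t0, knockoffs):
    """ImportanceVector from a list t0 (p,) and rows knockoffs (M, p)."""
    p = len(t0)
    names = [f"f{j}" for j in range(p)]
    return ImportanceVector(
        original=pd.Series(t0, index=names, dtype=float),
        knockoffs=pd.DataFrame(knockoffs, columns=names, dtype=float),
    )


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_kappa_tau(t0, tm):
    kappas, taus = [], []
    for j in range(len(t0)):
        vals = [t0[j]] + [row[j] for row in tm]
        k = max(range(len(vals)), key=lambda i: (vals[i], -i))
        rest = [v for i, v in enumerate(vals) if i != k]
        rest_sorted = sorted(rest)
        mid = len(rest_sorted)
        if mid % 2:
            med = rest_sorted[mid // 2]
        else:
            med = 0.5 * (rest_sorted[mid // 2 - 1] + rest_sorted[mid // 2])
        kappas.append(k)
        taus.append(vals[k] - med)
    return kappas, taus


def oracle_ratio(kappas, taus, t, M):
    num = 1 / M + sum(1 for k, tj in zip(kappas, taus) if k >= 1 and tj >= t) / M
    den = sum(1 for k, tj in zip(kappas, taus) if k == 0 and tj >= t)
    return num / den if den else math.inf


def oracle_threshold(kappas, taus, q, M):
    best = math.inf
    for t in sorted({tj for tj in taus if tj > 0}):
        if oracle_ratio(kappas, taus, t, M) <= q:
            best = min(best, t)
    return best


def oracle_selection(t0, tm, q):
    M = len(tm)
    kappas, taus = oracle_kappa_tau(t0, tm)
    thr = oracle_threshold(kappas, taus, q, M)
    if math.isinf(thr):
        return set()
    return {j for j in range(len(t0)) if kappas[j] == 0 and taus[j] >= thr}


def random_instance(rng, with_ties=True):
    p = rng.integers(2, 12)
    M = int(rng.choice([1, 3, 5]))
    t0 = rng.random(p) * 2
    tm = rng.random((M, p))
    # boost some originals so selections are non-trivial
    boost = rng.random(p) < 0.5
    t0[boost] += 1.0
    if with_ties:
        t0 = np.round(t0, 1)
        tm = np.round(tm, 1)
    return t0, tm, M


class TestKnockoffStatistic:
    def test_hand_evaluation_winner(self):
        iv = make_iv([0.9], [[0.1], [0.2], [0.3], [0.15], [0.25]])
        # median 0.2, max 0.3 -> W = 0.9 - 0.2
        assert knockoff_statistic(iv)[0] == pytest.approx(0.7)

    def test_hand_evaluation_loser(self):
        iv = make_iv([0.28], [[0.1], [0.2], [0.3], [0.15], [0.25]])
        assert knockoff_statistic(iv)[0] == 0.0

    def test_null_feature(self):
        iv = make_iv([0.0], [[0.0]] * 5)
        assert knockoff_statistic(iv)[0] == 0.0

    def test_tie_with_max_counts_as_win(self):
        iv = make_iv([0.3], [[0.1], [0.3], [0.2]])
        assert knockoff_statistic(iv)[0] == pytest.approx(0.1)


class TestKappaTau:
    def test_original_largest_matches_w(self):
        iv = make_iv([0.9, 0.5], [[0.1, 0.6], [0.2, 0.4], [0.3, 0.45]])
        kappa, tau = kappa_tau(iv)
        W = knockoff_statistic(iv)
        assert kappa[0] == 0 and tau[0] == pytest.approx(W[0])

    def test_knockoff_winner_hand_case(self):
        iv = make_iv([0.1], [[0.5], [0.2], [0.2], [0.2], [0.2]])
        kappa, tau = kappa_tau(iv)
        assert kappa[0] == 1
        # max 0.5 minus median of {0.1, 0.2, 0.2, 0.2, 0.2}
        assert tau[0] == pytest.approx(0.3)

    def test_all_equal_ties_to_original(self):
        iv = make_iv([0.4], [[0.4], [0.4]])
        kappa, tau = kappa_tau(iv)
        assert kappa[0] == 0 and tau[0] == 0.0

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t0, tm, M = random_instance(rng)
            iv = make_iv(t0, tm)
            kappa, tau = kappa_tau(iv)
            ok, ot = oracle_kappa_tau(list(t0), [list(r) for r in tm])
            assert list(kappa) == ok
            np.testing.assert_allclose(tau, ot, atol=1e-12)


class TestAdaptiveThreshold:
    def test_all_knockoff_wins_gives_infinite_threshold(self):
        kappa = np.array([1, 2, 1])
        tau = np.array([0.5, 0.4, 0.3])
        assert math.isinf(adaptive_threshold(kappa, tau, 0.2, M=5))

    def test_worked_instance_selects_at_half(self):
        kappa = np.array([0, 0, 0, 0, 1, 0])
        tau = np.array([5.0, 4.0, 3.0, 2.0, 6.0, 1.0])
        # at t=1: (1 + 1)/5 = 0.4 <= 0.5
        assert adaptive_threshold(kappa, tau, 0.5, M=1) == 1.0

    def test_worked_instance_fails_at_point_three(self):
        kappa = np.array([0, 0, 0, 0, 1, 0])
        tau = np.array([5.0, 4.0, 3.0, 2.0, 6.0, 1.0])
        assert math.isinf(adaptive_threshold(kappa, tau, 0.3, M=1))


class TestQValues:
    def test_top_stratum_of_16_features(self):
        # 16 originals sharing the top stratum, M=5: q = (1/5)/16
        t0 = [1.0] * 16
        tm = [[0.1] * 16] * 5
        stats = compute_stats(make_iv(t0, tm))
        np.testing.assert_allclose(stats.q, 0.0125)

    def test_top_stratum_of_18_features(self):
        t0 = [1.0] * 18
        tm = [[0.1] * 18] * 5
        stats = compute_stats(make_iv(t0, tm))
        np.testing.assert_allclose(stats.q, 0.2 / 18)

    def test_knockoff_winner_gets_q_one(self):
        iv = make_iv([0.1, 0.9], [[0.2, 0.3], [0.5, 0.2], [0.3, 0.1]])
        stats = compute_stats(iv)
        assert stats.kappa[0] == 3 or stats.kappa[0] >= 1
        assert stats.q[0] == 1.0

    def test_minimum_attainable_q(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t0, tm, M = random_instance(rng)
            stats = compute_stats(make_iv(t0, tm))
            s = np.sum(stats.kappa == 0)
            if s:
                assert stats.q.min() >= (1 / M) / max(s, 1) - 1e-12


class TestSelect:
    def test_infinite_threshold_selects_nothing(self):
        iv = make_iv([0.1, 0.2], [[0.5, 0.6], [0.4, 0.7]])
        res = select(compute_stats(iv), 0.2)
        assert res.selected == [] and math.isinf(res.threshold)

    def test_worked_instance_continuation(self):
        t0 = [6.0, 5.0, 4.0, 3.0, 0.0, 2.0]
        tm = [[1.0, 1.0, 1.0, 1.0, 6.0, 1.0]]
        res = select(compute_stats(make_iv(t0, tm)), 0.5)
        assert res.selected == ["f0", "f1", "f2", "f3", "f5"]

    def test_near_one_target_selects_all_winners(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t0, tm, M = random_instance(rng)
            stats = compute_stats(make_iv(t0, tm))
            res = select(stats, 0.999)
            oracle = oracle_selection(list(t0), [list(r) for r in tm], 0.999)
            assert {stats.features.index(f) for f in res.selected} == oracle

    def test_duality_and_monotonicity_against_oracle(self):
        rng = np.random.default_rng(3)
        grid = [round(0.01 * k, 2) for k in range(1, 21)]
        for _ in range(150):
            t0, tm, M = random_instance(rng)
            stats = compute_stats(make_iv(t0, tm))
            previous: set = set()
            for q in grid:
                res = select(stats, q)  # raises if W-route != q-route
                got = {stats.features.index(f) for f in res.selected}
                assert got == oracle_selection(list(t0), [list(r) for r in tm], q)
                assert got >= previous  # nondecreasing in q
                previous = got


class TestConsensusAndRanking:
    def test_three_of_five_rule(self):
        results = []
        for sel in (["a", "b"], ["a"], ["a", "c"], ["b"], ["b", "c"]):
            iv = make_iv([1.0], [[0.0]])
            r = select(compute_stats(iv), 0.5)
            r.selected = sel
            results.append(r)
        assert consensus(results, min_votes=3) == ["a", "b"]
        assert consensus(results, min_votes=1) == ["a", "b", "c"]
        assert consensus(results, min_votes=5) == []

    def test_rank_features_descending(self):
        assert rank_features(np.array([3.0, 1.0, 2.0])) == ["0", "2", "1"]

    def test_rank_ties_break_by_index(self):
        assert rank_features(np.array([0.5, 0.5])) == ["0", "1"]

    def test_ascending_reverses_descending_without_ties(self):
        s = pd.Series([0.3, 0.9, 0.1], index=["a", "b", "c"])
        assert rank_features(s, "ascending") == rank_features(s, "descending")[::-1]
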