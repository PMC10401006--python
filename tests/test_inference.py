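"""Nonparametric inference: exact enumeration oracles, cross-checks, calibration.

The oracles here enumerate arrangements directly (subsets, sign patterns,
group assignments) and never share code with the dynamic-programming /
approximation routines they check.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from clincrowd import inference as inf
from clincrowd.errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParametersError,
)

# ---------------------------------------------------------------------------
# Brute-force oracles


def oracle_rank_sum_p(a, b, sidedness):
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, N = len(a), len(pooled)
    mu = n1 * ranks.sum() / N
    w_obs = ranks[:n1].sum()
    hits = total = 0
    for comb in itertools.combinations(range(N), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if sidedness == "greater":
            hits += w >= w_obs - 1e-9
        elif sidedness == "less":
            hits += w <= w_obs + 1e-9
        else:
            hits += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    return hits / total


def oracle_signed_rank_p(d, sidedness):
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    hits = total = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if sidedness == "greater":
            hits += w >= w_obs - 1e-9
        elif sidedness == "less":
            hits += w <= w_obs + 1e-9
        else:
            hits += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    return hits / total


def oracle_jt_stat(groups):
    s = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        for x in gi:
            for y in gj:
                s += (x < y) + 0.5 * (x == y)
    return s


def oracle_jt_p(groups, sidedness):
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    t_obs = oracle_jt_stat(groups)
    mu = (N * N - sum(s * s for s in sizes)) / 4.0
    hits = total = 0

    def assignments(remaining, sizes_left):
        if len(sizes_left) == 1:
            yield [remaining]
            return
        for comb in itertools.combinations(remaining, sizes_left[0]):
            rest = [i for i in remaining if i not in set(comb)]
            for tail in assignments(rest, sizes_left[1:]):
                yield [list(comb)] + tail

    for assign in assignments(list(range(N)), sizes):
        t = oracle_jt_stat([pooled[idx] for idx in assign])
        total += 1
        if sidedness == "greater":
            hits += t >= t_obs - 1e-9
        elif sidedness == "less":
            hits += t <= t_obs + 1e-9
        else:
            hits += abs(t - mu) >= abs(t_obs - mu) - 1e-9
    return hits / total


# ---------------------------------------------------------------------------
# Rank-sum


class TestRankSum:
    def test_identical_samples_symmetric(self):
        r = inf.wilcoxon_rank_sum([1.0, 2.0, 3.5], [1.5, 2.5, 3.0])
        assert r.mode == "exact"
        assert r.p_value <= 1.0

    def test_separated_samples_exact_tail(self):
        r = inf.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.mode == "exact"
        assert r.statistic == 6.0
        assert r.p_value == pytest.approx(2 / 20)  # 2 of C(6,3) arrangements

    @pytest.mark.parametrize("sidedness", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration_oracle(self, sidedness):
        rng = np.random.default_rng(10)
        for _ in range(40):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 9 - n1))
            a, b = rng.uniform(0, 1, n1), rng.uniform(0, 1, n2)
            r = inf.wilcoxon_rank_sum(a, b, sidedness)
            assert r.mode == "exact"
            assert r.p_value == pytest.approx(
                oracle_rank_sum_p(a, b, sidedness), abs=1e-12
            )

    def test_approx_matches_scipy_mannwhitney(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b = rng.normal(0, 1, 30), rng.normal(0.3, 1, 20)
            r = inf.wilcoxon_rank_sum(a, b)
            ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
            assert r.mode == "normal-approx"
            assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample(self):
        with pytest.raises(InvalidInputError):
            inf.wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Signed-rank


class TestSignedRank:
    def test_antisymmetric_differences(self):
        # tied magnitudes, so exact mode is forced explicitly
        r = inf.wilcoxon_signed_rank([-3, -1, 1, 3], mode="exact")
        assert r.mode == "exact"
        assert r.p_value == 1.0

    def test_all_positive_one_sided(self):
        r = inf.wilcoxon_signed_rank([1, 2, 3, 4, 5], sidedness="greater")
        assert r.mode == "exact"
        assert r.p_value == pytest.approx(1 / 32)

    @pytest.mark.parametrize("sidedness", ["two-sided", "greater", "less"])
    def test_exact_matches_sign_flip_oracle(self, sidedness):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n = int(rng.integers(3, 11))
            d = rng.normal(0.2, 1, n)
            r = inf.wilcoxon_signed_rank(d, sidedness)
            assert r.mode == "exact"
            assert r.p_value == pytest.approx(
                oracle_signed_rank_p(d, sidedness), abs=1e-12
            )

    def test_zeros_dropped(self):
        r = inf.wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -3.0])
        assert r.n == (3,)

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            inf.wilcoxon_signed_rank([0.0, 0.0])

    def test_approx_matches_scipy(self):
        rng = np.random.default_rng(13)
        d = rng.normal(0.3, 1, 40)
        r = inf.wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, correction=True, method="approx")
        assert r.mode == "normal-approx"
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra


class TestJonckheereTerpstra:
    def test_perfectly_ordered_groups(self):
        r = inf.jonckheere_terpstra([[1, 2], [3, 4], [5, 6]], sidedness="greater")
        assert r.mode == "exact"
        assert r.statistic == 12.0  # maximal: all 12 cross-pairs concordant
        assert r.p_value == pytest.approx(1 / 90)  # 1 of C(6,2)*C(4,2) assignments

    def test_reversal_maps_to_complement(self):
        groups = [[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]]
        fwd = inf.jonckheere_terpstra(groups)
        rev = inf.jonckheere_terpstra(groups[::-1])
        assert fwd.statistic + rev.statistic == pytest.approx(12.0)  # max = 2*2*3

    @pytest.mark.parametrize("sidedness", ["two-sided", "greater", "less"])
    def test_exact_matches_assignment_oracle(self, sidedness):
        rng = np.random.default_rng(14)
        for _ in range(25):
            sizes = rng.integers(2, 4, size=3)
            while sizes.sum() > 9:
                sizes = rng.integers(2, 4, size=3)
            groups = [rng.uniform(0, 1, s) for s in sizes]
            r = inf.jonckheere_terpstra(groups, sidedness, mode="exact")
            assert r.p_value == pytest.approx(
                oracle_jt_p(groups, sidedness), abs=1e-12
            )

    def test_permutation_close_to_exact(self):
        rng = np.random.default_rng(15)
        groups = [rng.uniform(0, 1, 3) for _ in range(3)]
        ex = inf.jonckheere_terpstra(groups, mode="exact")
        pm = inf.jonckheere_terpstra(groups, mode="permutation", n_perm=4000, seed=2)
        assert pm.p_value == pytest.approx(ex.p_value, abs=0.03)

    def test_permutation_seed_reproducible(self):
        rng = np.random.default_rng(16)
        groups = [rng.normal(size=8) for _ in range(4)]
        p1 = inf.jonckheere_terpstra(groups, mode="permutation", n_perm=500, seed=9)
        p2 = inf.jonckheere_terpstra(groups, mode="permutation", n_perm=500, seed=9)
        assert p1.p_value == p2.p_value

    def test_too_few_groups(self):
        with pytest.raises(InvalidInputError):
            inf.jonckheere_terpstra([[1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_perfect_monotone(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert inf.spearman(x, x).statistic == pytest.approx(1.0)
        assert inf.spearman(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_tied_data_matches_hand_midranks(self):
        # x = (1,2,2,4,5,6) -> midranks (1,2.5,2.5,4,5,6); y has one tie pair
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [10.0, 30.0, 20.0, 20.0, 50.0, 40.0]
        rx = np.array([1, 2.5, 2.5, 4, 5, 6])
        ry = np.array([1, 4, 2.5, 2.5, 6, 5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert inf.spearman(x, y).statistic == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=25), rng.normal(size=25)
        r = inf.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input(self):
        with pytest.raises(DegenerateInputError):
            inf.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Hodges-Lehmann CI


class TestRankSumCI:
    def test_pure_shift_point_estimate(self):
        a = np.array([1.0, 2.0, 4.0, 7.0])
        ci = inf.rank_sum_ci(a, a + 5.0)
        assert ci.estimate == pytest.approx(5.0)
        assert ci.lower <= ci.estimate <= ci.upper

    def test_exact_endpoints_match_test_inversion(self):
        """CI endpoints equal the bracketing order statistics of the
        pairwise differences under direct inversion of the exact test."""
        rng = np.random.default_rng(18)

        def inversion_bounds(a, b, conf):
            n1, n2 = len(a), len(b)
            alpha = 1 - conf
            diffs = np.sort((b[None, :] - a[:, None]).ravel())
            us = np.array(
                [
                    sum(c) - n2 * (n2 + 1) / 2
                    for c in itertools.combinations(range(1, n1 + n2 + 1), n2)
                ]
            )

            def rejected(delta):
                u = float(((b[None, :] - a[:, None]) > delta).sum()) + 0.5 * float(
                    ((b[None, :] - a[:, None]) == delta).sum()
                )
                return (us <= u).mean() <= alpha / 2 or (us >= u).mean() <= alpha / 2

            d = np.unique(diffs)
            cands = sorted(
                list(d) + list((d[:-1] + d[1:]) / 2) + [d[0] - 1, d[-1] + 1]
            )
            acc = [c for c in cands if not rejected(c)]
            lo = [x for x in diffs if x <= min(acc)]
            hi = [x for x in diffs if x >= max(acc)]
            return (max(lo) if lo else diffs[0]), (min(hi) if hi else diffs[-1])

        for _ in range(25):
            n1 = int(rng.integers(3, 7))
            n2 = int(rng.integers(3, 7))
            a, b = rng.normal(0, 1, n1), rng.normal(0.5, 1, n2)
            ci = inf.rank_sum_ci(a, b, confidence=0.95)
            lo, hi = inversion_bounds(a, b, 0.95)
            assert ci.mode == "exact"
            assert ci.lower == pytest.approx(lo, abs=1e-12)
            assert ci.upper == pytest.approx(hi, abs=1e-12)

    def test_large_sample_mode_coverage(self):
        """95% CI covers the true shift in most replicates and always
        brackets its own point estimate."""
        rng = np.random.default_rng(19)
        covered = 0
        for _ in range(20):
            a = rng.normal(0, 1, 40)
            b = rng.normal(2.0, 1, 40)
            ci = inf.rank_sum_ci(a, b)
            assert ci.mode == "normal-approx"
            assert ci.lower <= ci.estimate <= ci.upper
            covered += ci.lower <= 2.0 <= ci.upper
        assert covered >= 17


# ---------------------------------------------------------------------------
# t test


class TestTwoSampleT:
    def test_identical_samples(self):
        r = inf.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_constant_equal_and_unequal(self):
        assert inf.two_sample_t([2.0, 2.0], [2.0, 2.0]).p_value == 1.0
        with pytest.raises(DegenerateInputError):
            inf.two_sample_t([0.0, 0.0], [1.0, 1.0])

    def test_welch_matches_formula_and_scipy(self):
        a = np.array([19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0])
        b = np.array([28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7])
        r = inf.two_sample_t(a, b)
        se = math.sqrt(a.var(ddof=1) / 10 + b.var(ddof=1) / 10)
        assert r.statistic == pytest.approx((a.mean() - b.mean()) / se, abs=1e-12)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_pooled_variant_matches_scipy(self):
        rng = np.random.default_rng(20)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 9)
        r = inf.two_sample_t(a, b, pooled=True)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)


# ---------------------------------------------------------------------------
# Power simulation


class TestPowerRankSum:
    def test_null_calibration(self):
        p = inf.power_rank_sum(0.0, n1=30, n2=15, alpha=0.05, n_sim=1000, seed=1)
        assert abs(p - 0.05) < 0.025

    def test_monotone_in_effect_size(self):
        grid = [0.0, 0.5, 1.0, 2.0]
        powers = [
            inf.power_rank_sum(d, n1=20, n2=20, n_sim=400, seed=3) for d in grid
        ]
        assert all(p2 >= p1 - 0.02 for p1, p2 in zip(powers, powers[1:]))

    def test_large_effect_saturates(self):
        assert inf.power_rank_sum(3.0, n1=20, n2=20, n_sim=400, seed=4) > 0.99


# ---------------------------------------------------------------------------
# Permutation-null invariance


class TestInvariances:
    def test_permutation_p_invariant_to_within_group_relabeling(self):
        rng = np.random.default_rng(21)
        groups = [rng.normal(size=6) for _ in range(3)]
        shuffled = [np.array(g)[::-1] for g in groups]
        p1 = inf.jonckheere_terpstra(groups, mode="permutation", n_perm=300, seed=5)
        p2 = inf.jonckheere_terpstra(shuffled, mode="permutation", n_perm=300, seed=5)
        assert p1.statistic == p2.statistic
        assert p1.p_value == p2.p_value

    def test_exact_p_values_are_rational_in_arrangements(self):
        a, b = [1.0, 2.0, 5.0], [3.0, 4.0]
        r = inf.wilcoxon_rank_sum(a, b)
        n_arr = math.comb(5, 3)
        assert (r.p_value * n_arr) == pytest.approx(round(r.p_value * n_arr))
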