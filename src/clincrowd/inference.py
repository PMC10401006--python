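"""Nonparametric tests and interval estimates used by the trial-level analysis.

Implemented from first principles: Wilcoxon rank-sum and signed-rank with
exact small-sample null distributions (dynamic programming over rank sums),
the Jonckheere-Terpstra ordered-alternative test (exact enumeration for tiny
inputs, seeded Monte-Carlo permutation, or tie-corrected normal
approximation), Spearman rank correlation, the Hodges-Lehmann location-shift
estimate with distribution-inverted confidence interval, Welch's t, and a
simulation-based power calculation for the rank-sum design.

All tests default to two-sided p-values.  Exact-mode p-values are exact
rational multiples of 1/(number of arrangements); two-sided exact tails are
symmetric about the null mean of the statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidInputError, InvalidParametersError

TWO_SIDED = "two-sided"
GREATER = "greater"
LESS = "less"
_SIDES = (TWO_SIDED, GREATER, LESS)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    sidedness: str
    n: tuple
    mode: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise InvalidInputError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ShiftEstimate:
    """Hodges-Lehmann location-shift estimate (b relative to a) with CI."""

    estimate: float
    lower: float
    upper: float
    confidence: float
    mode: str


def _check_side(sidedness: str) -> None:
    if sidedness not in _SIDES:
        raise InvalidParametersError(f"sidedness must be one of {_SIDES}")


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _has_ties(x: np.ndarray) -> bool:
    return len(np.unique(x)) < len(x)


def _tie_sizes(x: np.ndarray) -> np.ndarray:
    _, counts = np.unique(x, return_counts=True)
    return counts


# ---------------------------------------------------------------------------
# Exact null distributions via dynamic programming on doubled midranks
# (midranks are multiples of 1/2, so doubling keeps everything integer).


def _choose_sum_distribution(doubled: Sequence[int], n_pick: int) -> dict:
    """Distribution of the sum over all size-``n_pick`` subsets of ``doubled``.

    Returns {sum: count}; counts total C(len(doubled), n_pick).
    """
    dp = [dict() for _ in range(n_pick + 1)]
    dp[0][0] = 1
    for r in doubled:
        hi = min(n_pick, len(dp) - 1)
        for j in range(hi, 0, -1):
            prev = dp[j - 1]
            cur = dp[j]
            for s, c in prev.items():
                cur[s + r] = cur.get(s + r, 0) + c
    return dp[n_pick]


def _subset_sum_distribution(doubled: Sequence[int]) -> dict:
    """Distribution of the sum over all 2^n subsets of ``doubled``."""
    dist = {0: 1}
    for r in doubled:
        nxt = dict(dist)
        for s, c in dist.items():
            nxt[s + r] = nxt.get(s + r, 0) + c
        dist = nxt
    return dist


def _tail_p(dist: dict, obs: int, center_num: int, center_den: int, sidedness: str) -> float:
    """Tail probability from an integer-valued exact distribution.

    ``center_num/center_den`` is the null mean of the statistic; the
    two-sided tail collects arrangements at least as far from it as ``obs``.
    All comparisons are in exact integer arithmetic.
    """
    total = sum(dist.values())
    if sidedness == GREATER:
        count = sum(c for s, c in dist.items() if s >= obs)
    elif sidedness == LESS:
        count = sum(c for s, c in dist.items() if s <= obs)
    else:
        d_obs = abs(obs * center_den - center_num)
        count = sum(
            c for s, c in dist.items() if abs(s * center_den - center_num) >= d_obs
        )
    return count / total


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    sidedness: str = TWO_SIDED,
    mode: str = "auto",
    exact_limit: int = 12,
) -> TestResult:
    """Two-sample Wilcoxon rank-sum test; statistic is the rank sum of ``a``.

    Exact enumeration (all C(N, n_a) rank assignments) when N <= 12 with no
    ties; otherwise normal approximation with midrank tie correction and
    continuity correction.  ``sidedness='greater'`` means a tends larger.
    """
    _check_side(sidedness)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        # every arrangement yields the same statistic: exact p is 1
        return TestResult("wilcoxon-rank-sum", w, 1.0, sidedness, (n1, n2), "exact")
    ties = _has_ties(pooled)

    use_exact = mode == "exact" or (
        mode == "auto" and n1 + n2 <= exact_limit and not ties
    )
    if use_exact:
        doubled = np.rint(2 * ranks).astype(int)
        dist = _choose_sum_distribution(doubled.tolist(), n1)
        w2 = int(round(2 * w))
        total2 = int(doubled.sum())
        # null mean of doubled statistic: n1 * total2 / N
        p = _tail_p(dist, w2, n1 * total2, n1 + n2, sidedness)
        return TestResult("wilcoxon-rank-sum", w, p, sidedness, (n1, n2), "exact")

    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    t = _tie_sizes(pooled)
    tie_term = ((t**3 - t).sum()) / (N * (N - 1.0))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        raise DegenerateInputError("all pooled values identical")
    sd = math.sqrt(var)
    if sidedness == TWO_SIDED:
        z = max(abs(w - mu) - 0.5, 0.0) / sd
        p = 2.0 * sps.norm.sf(z)
    elif sidedness == GREATER:
        z = (w - mu - 0.5) / sd
        p = sps.norm.sf(z)
    else:
        z = (w - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    return TestResult(
        "wilcoxon-rank-sum", w, min(p, 1.0), sidedness, (n1, n2), "normal-approx"
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(
    differences: Sequence[float],
    sidedness: str = TWO_SIDED,
    mode: str = "auto",
    zero_method: str = "wilcox",
    exact_limit: int = 15,
) -> TestResult:
    """One-sample/paired signed-rank test on ``differences``.

    Statistic is W+, the sum of ranks of positive differences.  Zeros are
    dropped (Wilcoxon's convention; ``zero_method='pratt'`` ranks them first
    and then discards their ranks).  Exact sign-flip enumeration when the
    nonzero count is <= 15 with no tied magnitudes, else normal
    approximation with tie correction and continuity correction.
    """
    _check_side(sidedness)
    if zero_method not in ("wilcox", "pratt"):
        raise InvalidParametersError("zero_method must be 'wilcox' or 'pratt'")
    d = np.asarray(differences, dtype=float)
    nonzero = d[d != 0]
    n = nonzero.size
    n0 = d.size - n
    if n == 0:
        raise DegenerateInputError("all differences are zero")

    if zero_method == "wilcox":
        ranks = _midranks(np.abs(nonzero))
    else:
        ranks = _midranks(np.abs(d))[d != 0]
    wplus = float(ranks[nonzero > 0].sum())
    ties = _has_ties(np.abs(nonzero))

    use_exact = zero_method == "wilcox" and (
        mode == "exact" or (mode == "auto" and n <= exact_limit and not ties)
    )
    if use_exact:
        doubled = np.rint(2 * ranks).astype(int)
        dist = _subset_sum_distribution(doubled.tolist())
        w2 = int(round(2 * wplus))
        total2 = int(doubled.sum())
        p = _tail_p(dist, w2, total2, 2, sidedness)  # mean of doubled W+ is total2/2
        return TestResult("wilcoxon-signed-rank", wplus, p, sidedness, (n,), "exact")

    if zero_method == "wilcox":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
    else:
        m = n + n0
        mu = (m * (m + 1) - n0 * (n0 + 1)) / 4.0
        var = (m * (m + 1) * (2 * m + 1) - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0
    t = _tie_sizes(np.abs(nonzero))
    var -= (t**3 - t).sum() / 48.0
    if var <= 0:
        raise DegenerateInputError("degenerate signed-rank variance")
    sd = math.sqrt(var)
    if sidedness == TWO_SIDED:
        z = max(abs(wplus - mu) - 0.5, 0.0) / sd
        p = 2.0 * sps.norm.sf(z)
    elif sidedness == GREATER:
        z = (wplus - mu - 0.5) / sd
        p = sps.norm.sf(z)
    else:
        z = (wplus - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    return TestResult(
        "wilcoxon-signed-rank", wplus, min(p, 1.0), sidedness, (n,), "normal-approx"
    )


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra


def _jt_doubled(groups) -> int:
    """Doubled JT statistic: sum over ordered pairs of 2*(x<y) + (x==y)."""
    s = 0
    for gi, gj in itertools.combinations(groups, 2):
        xi = gi[:, None]
        xj = gj[None, :]
        s += 2 * int((xi < xj).sum()) + int((xi == xj).sum())
    return s


def _jt_center4(sizes: Sequence[int], N: int) -> int:
    # 4 * E[JT] = N^2 - sum n_i^2 (holds with or without ties)
    return N * N - sum(s * s for s in sizes)


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    sidedness: str = TWO_SIDED,
    mode: str = "auto",
    n_perm: int = 10_000,
    seed: int = 0,
    exact_limit: int = 50_000,
) -> TestResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    Statistic = sum over ordered group pairs (i < j) of Mann-Whitney counts
    #(x_i < x_j) + 0.5 #(x_i == x_j); large values indicate an increasing
    trend.  ``mode='auto'`` enumerates all distinct group assignments when
    their number is <= ``exact_limit``, else uses the tie-corrected normal
    approximation; ``mode='permutation'`` draws ``n_perm`` seeded label
    permutations.
    """
    _check_side(sidedness)
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise InvalidInputError("need at least 3 ordered groups")
    if any(g.size == 0 for g in groups):
        raise InvalidInputError("all groups must be non-empty")
    sizes = [g.size for g in groups]
    N = sum(sizes)
    pooled = np.concatenate(groups)
    jt2 = _jt_doubled(groups)
    jt = jt2 / 2.0
    center4 = _jt_center4(sizes, N)
    if np.all(pooled == pooled[0]):
        return TestResult(
            "jonckheere-terpstra", jt, 1.0, sidedness, tuple(sizes), "exact"
        )

    n_arrangements = math.factorial(N)
    for s in sizes:
        n_arrangements //= math.factorial(s)

    if mode == "exact" or (mode == "auto" and n_arrangements <= exact_limit):
        dist = {}
        idx_all = list(range(N))

        def recurse(remaining, gi, chosen):
            if gi == len(sizes) - 1:
                arr = [pooled[list(c)] for c in chosen] + [
                    pooled[list(remaining)]
                ]
                s2 = _jt_doubled(arr)
                dist[s2] = dist.get(s2, 0) + 1
                return
            for comb in itertools.combinations(remaining, sizes[gi]):
                rest = [i for i in remaining if i not in set(comb)]
                recurse(rest, gi + 1, chosen + [comb])

        recurse(idx_all, 0, [])
        # center of doubled statistic is center4/2
        p = _tail_p(dist, jt2, center4, 2, sidedness)
        return TestResult("jonckheere-terpstra", jt, p, sidedness, tuple(sizes), "exact")

    if mode == "permutation":
        rng = np.random.default_rng(seed)
        bounds = np.cumsum([0] + sizes)
        d_obs = abs(2 * jt2 - center4)
        count = 0
        base = np.sort(pooled)  # canonical order: p depends only on the multiset
        for _ in range(n_perm):
            perm = rng.permutation(base)
            arr = [perm[bounds[i] : bounds[i + 1]] for i in range(len(sizes))]
            s2 = _jt_doubled(arr)
            if sidedness == GREATER:
                count += s2 >= jt2
            elif sidedness == LESS:
                count += s2 <= jt2
            else:
                count += abs(2 * s2 - center4) >= d_obs
        p = (1 + count) / (n_perm + 1)
        return TestResult(
            "jonckheere-terpstra", jt, p, sidedness, tuple(sizes), "permutation"
        )

    # tie-corrected normal approximation (Hollander & Wolfe)
    mu = center4 / 4.0
    t = _tie_sizes(pooled).astype(float)
    n_arr = np.array(sizes, dtype=float)
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - (n_arr * (n_arr - 1) * (2 * n_arr + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (n_arr * (n_arr - 1) * (n_arr - 2)).sum()
        * (t * (t - 1) * (t - 2)).sum()
        / (36.0 * N * (N - 1) * (N - 2))
    )
    term3 = (
        (n_arr * (n_arr - 1)).sum() * (t * (t - 1)).sum() / (8.0 * N * (N - 1))
    )
    var = term1 + term2 + term3
    if var <= 0:
        raise DegenerateInputError("degenerate JT variance (constant data?)")
    sd = math.sqrt(var)
    if sidedness == TWO_SIDED:
        z = max(abs(jt - mu) - 0.5, 0.0) / sd
        p = 2.0 * sps.norm.sf(z)
    elif sidedness == GREATER:
        z = (jt - mu - 0.5) / sd
        p = sps.norm.sf(z)
    else:
        z = (jt - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    return TestResult(
        "jonckheere-terpstra", jt, min(p, 1.0), sidedness, tuple(sizes), "normal-approx"
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation


def spearman(x: Sequence[float], y: Sequence[float], sidedness: str = TWO_SIDED) -> TestResult:
    """Spearman correlation: Pearson correlation of midranks, t-approximation p."""
    _check_side(sidedness)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input has no rank correlation")
    rx, ry = _midranks(x), _midranks(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    r_cl = min(max(r, -1.0), 1.0)
    if abs(r_cl) == 1.0:
        p = 0.0
    else:
        tstat = r_cl * math.sqrt((n - 2) / (1.0 - r_cl * r_cl))
        if sidedness == TWO_SIDED:
            p = 2.0 * sps.t.sf(abs(tstat), n - 2)
        elif sidedness == GREATER:
            p = sps.t.sf(tstat, n - 2)
        else:
            p = sps.t.cdf(tstat, n - 2)
    return TestResult("spearman", r_cl, min(p, 1.0), sidedness, (n,), "t-approx")


# ---------------------------------------------------------------------------
# Hodges-Lehmann shift estimate with rank-sum-inverted CI


def rank_sum_ci(
    a: Sequence[float],
    b: Sequence[float],
    confidence: float = 0.95,
    exact_limit: int = 12,
) -> ShiftEstimate:
    """Location shift of ``b`` relative to ``a`` (positive = b larger).

    Point estimate is the median of the n_a*n_b pairwise differences
    b_j - a_i; the CI endpoints are order statistics of those differences,
    with the cut index taken from the exact Mann-Whitney distribution for
    small tie-free samples and from the normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    if not 0.0 < confidence < 1.0:
        raise InvalidParametersError("confidence must lie in (0, 1)")
    n1, n2 = a.size, b.size
    mn = n1 * n2
    diffs = np.sort((b[None, :] - a[:, None]).ravel())
    est = float(np.median(diffs))
    alpha = 1.0 - confidence
    N = n1 + n2

    pooled = np.concatenate([a, b])
    if N <= exact_limit and not _has_ties(pooled):
        # exact cdf of U = #{(i,j): b_j > a_i} from rank-sum DP (untied)
        doubled = list(range(2, 2 * N + 1, 2))  # doubled ranks 1..N
        dist = _choose_sum_distribution(doubled, n2)
        total = sum(dist.values())
        # U = W_b - n2(n2+1)/2 ; doubled: U2 = s - n2(n2+1)
        offset = n2 * (n2 + 1)
        cdf = {}
        acc = 0
        for s in sorted(dist):
            acc += dist[s]
            cdf[(s - offset) // 2] = acc / total
        # exclude the k smallest/largest differences, k = max{u: P(U <= u) <= a/2}
        k = 0
        for u in sorted(cdf):
            if cdf[u] <= alpha / 2:
                k = u
        mode = "exact"
    else:
        z = sps.norm.ppf(1.0 - alpha / 2)
        k = int(math.floor(mn / 2.0 - z * math.sqrt(mn * (N + 1) / 12.0)))
        mode = "normal-approx"
    k = max(0, min(k, (mn - 1) // 2))
    lower = float(diffs[k]) if k < mn else float(diffs[0])
    upper = float(diffs[mn - 1 - k])
    return ShiftEstimate(est, lower, upper, confidence, mode)


# ---------------------------------------------------------------------------
# Student / Welch t


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    sidedness: str = TWO_SIDED,
    pooled: bool = False,
) -> TestResult:
    """Two-sample t test, Welch by default (``pooled=True`` for Student).

    Both samples constant and equal -> t = 0, p = 1; constant and unequal
    signals degenerate input (infinite evidence under the model).
    """
    _check_side(sidedness)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = a.size, b.size
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(
                "welch-t" if not pooled else "student-t",
                0.0,
                1.0,
                sidedness,
                (n1, n2),
                "analytic",
            )
        raise DegenerateInputError("zero variance with unequal means")
    if pooled:
        sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
        method = "student-t"
    else:
        se = math.sqrt(va / n1 + vb / n2)
        df = (va / n1 + vb / n2) ** 2 / (
            (va / n1) ** 2 / (n1 - 1) + (vb / n2) ** 2 / (n2 - 1)
        )
        method = "welch-t"
    t = (a.mean() - b.mean()) / se
    if sidedness == TWO_SIDED:
        p = 2.0 * sps.t.sf(abs(t), df)
    elif sidedness == GREATER:
        p = sps.t.sf(t, df)
    else:
        p = sps.t.cdf(t, df)
    return TestResult(method, float(t), min(p, 1.0), sidedness, (n1, n2), "analytic")


# ---------------------------------------------------------------------------
# Simulation-based power for the rank-sum trial-level design


def power_rank_sum(
    d: float,
    n1: int = 56,
    n2: int = 28,
    alpha: float = 0.05,
    n_sim: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided rank-sum test under a normal shift d.

    Samples are N(0,1) vs N(d,1) at the trial-level sizes (56 vs 28 by
    default); returns the fraction of replicates with p <= alpha.
    """
    if n1 <= 0 or n2 <= 0 or n_sim <= 0:
        raise InvalidParametersError("sizes and n_sim must be positive")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        a = rng.normal(0.0, 1.0, n1)
        b = rng.normal(d, 1.0, n2)
        if wilcoxon_rank_sum(a, b).p_value <= alpha:
            hits += 1
    return hits / n_sim
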