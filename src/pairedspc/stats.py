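"""Exact and asymptotic hypothesis tests used across the pipeline.

Every test that can be enumerated at desk scale has an exact path computed in
integer arithmetic (distribution counts over sign patterns, rank subsets,
hypergeometric tables or permutations), so p-values in the exact regime are
rational numbers rendered to float once. Above the configurable exact limits
the standard tie-corrected normal (or Student-t) approximations take over.

Two-sided conventions:

* signed-rank / rank-sum: doubled smaller tail, capped at 1;
* Fisher: sum of hypergeometric point probabilities no larger than the
  observed table's (the ``fisher.test`` convention), compared in exact
  integer arithmetic so ties are unambiguous;
* Kendall tau-b: permutation tail ``P(|T| >= |t_obs|)`` in the exact regime,
  tie-corrected normal approximation on the C-D statistic otherwise.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "wilcoxon_signed_rank_batch",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "kendall_tau_b",
    "t_test_two_tailed",
    "bh_fdr",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``exact`` is True only when the p-value came from full enumeration;
    ``degenerate`` marks inputs on which the statistic is undefined or
    carries no information (all-zero differences, constant vectors, empty
    margins), for which ``p`` is reported as 1.
    """

    statistic: float
    p: float
    method: str
    n: int
    exact: bool
    degenerate: bool = False
    odds_ratio: float | None = None


def _two_sided_from_counts(n_le: int, n_ge: int, n_total: int) -> float:
    """Doubled smaller tail from integer tail counts, capped at 1."""
    tail = min(n_le, n_ge)
    p = Fraction(2 * tail, n_total)
    return float(min(p, Fraction(1)))


def _signed_rank_distribution(weights: np.ndarray) -> np.ndarray:
    """Counts of subset-sums of ``weights`` (integer rank weights).

    Counts stay exact in float64 (<= 2**25 < 2**53). Cached by tie
    pattern, since batch callers (per-probe gene tests) reuse the same
    untied rank vector thousands of times.
    """
    return _signed_rank_distribution_cached(tuple(int(w) for w in weights))


@functools.lru_cache(maxsize=256)
def _signed_rank_distribution_cached(weights: tuple[int, ...]) -> np.ndarray:
    weights = np.asarray(weights, dtype=np.int64)
    total = int(weights.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for w in weights:
        w = int(w)
        shifted = np.zeros_like(counts)
        shifted[w:] = counts[: counts.size - w]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(diffs, exact_limit: int = 25) -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment). Ties among |differences| receive mid-ranks. Exact null
    enumeration over the 2**n sign patterns (via a subset-sum distribution
    on doubled ranks, which is exact for mid-ranks) is used for
    ``n <= exact_limit``; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("diffs must be one-dimensional")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", 0, True, degenerate=True)
    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        # doubled mid-ranks are integers; DP over the 2**n sign patterns
        weights = np.rint(2 * ranks).astype(np.int64)
        counts = _signed_rank_distribution(weights)
        obs = int(round(2 * w_plus))
        n_le = int(counts[: obs + 1].sum())
        n_ge = int(counts[obs:].sum())
        p = _two_sided_from_counts(n_le, n_ge, 2**n)
        return TestResult(w_plus, p, "wilcoxon_signed_rank", n, True)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon_signed_rank", n, False, degenerate=True)
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = float(min(1.0, 2 * _sps.norm.sf(abs(z))))
    return TestResult(w_plus, p, "wilcoxon_signed_rank", n, False)


def wilcoxon_signed_rank_batch(diffs, exact_limit: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise signed-rank tests on a matrix of paired differences.

    Semantically identical to calling :func:`wilcoxon_signed_rank` per
    row; rows without zero differences or |difference| ties share one
    exact null distribution and are evaluated vectorized, other rows fall
    back to the scalar path. Returns ``(w_plus, p)`` arrays.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 2:
        raise ValueError("diffs must be two-dimensional")
    n_rows, n = d.shape
    w_out = np.empty(n_rows)
    p_out = np.empty(n_rows)
    has_zero = (d == 0).any(axis=1)
    ad = np.abs(d)
    sorted_ad = np.sort(ad, axis=1)
    has_tie = (np.diff(sorted_ad, axis=1) == 0).any(axis=1)
    fast = ~(has_zero | has_tie)
    slow_idx = np.flatnonzero(~fast)
    for i in slow_idx:
        res = wilcoxon_signed_rank(d[i], exact_limit=exact_limit)
        w_out[i], p_out[i] = res.statistic, res.p
    if fast.any():
        sub = d[fast]
        order = np.argsort(np.abs(sub), axis=1, kind="stable")
        ranks = np.empty_like(sub)
        np.put_along_axis(ranks, order, np.arange(1, n + 1, dtype=float)[None, :], axis=1)
        w = np.where(sub > 0, ranks, 0.0).sum(axis=1)
        if n <= exact_limit:
            counts = _signed_rank_distribution(2 * np.arange(1, n + 1))
            cdf = np.cumsum(counts)
            sf = np.cumsum(counts[::-1])[::-1]
            obs = np.rint(2 * w).astype(np.int64)
            n_le = cdf[obs]
            n_ge = sf[obs]
            p = np.minimum(1.0, 2 * np.minimum(n_le, n_ge) / float(2**n))
        else:
            mean = n * (n + 1) / 4.0
            var = n * (n + 1) * (2 * n + 1) / 24.0
            z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
            p = np.minimum(1.0, 2 * _sps.norm.sf(np.abs(z)))
        w_out[fast] = w
        p_out[fast] = p
    return w_out, p_out


def _rank_sum_distribution(weights: np.ndarray, k: int) -> np.ndarray:
    """Counts of k-subsets of ``weights`` by subset sum (DP, exact floats)."""
    total = int(weights.sum())
    counts = np.zeros((k + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for w in weights:
        w = int(w)
        upd = counts.copy()
        upd[1:, w:] += counts[:-1, : total + 1 - w]
        counts = upd
    return counts[k]


def wilcoxon_rank_sum(x, y, exact_limit: int = 20) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Statistic is the rank sum of the first sample over the pooled mid-rank
    vector. Exact enumeration over the C(n, n_x) group assignments for
    pooled ``n <= exact_limit``; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    n = nx + ny
    ranks = _sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())
    if n <= exact_limit:
        weights = np.rint(2 * ranks).astype(np.int64)
        dist = _rank_sum_distribution(weights, nx)
        obs = int(round(2 * w))
        n_le = int(dist[: obs + 1].sum())
        n_ge = int(dist[obs:].sum())
        p = _two_sided_from_counts(n_le, n_ge, math.comb(n, nx))
        return TestResult(w, p, "wilcoxon_rank_sum", n, True)
    mean = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n) * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(w, 1.0, "wilcoxon_rank_sum", n, False, degenerate=True)
    z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
    p = float(min(1.0, 2 * _sps.norm.sf(abs(z))))
    return TestResult(w, p, "wilcoxon_rank_sum", n, False)


def fisher_exact(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table ``[[a, b], [c, d]]``.

    Point probabilities are hypergeometric with margins fixed; the
    two-sided p sums every table in the support whose point probability is
    no larger than the observed one, decided in exact integer arithmetic
    (no floating tie tolerance). The odds ratio is the sample cross-product
    ``(a*d)/(b*c)``; a zero off-diagonal cell yields +inf, a zero diagonal
    cell 0, and an all-informative-zero table NaN with the degenerate flag.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b, c, d = (int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative integers")
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if a * d == 0 and b * c == 0:
        oratio = math.nan
    elif b * c == 0:
        oratio = math.inf
    else:
        oratio = (a * d) / (b * c)
    if row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return TestResult(
            math.nan, 1.0, "fisher_exact", n_total, True, degenerate=True, odds_ratio=oratio
        )
    lo, hi = max(0, row1 + col1 - n_total), min(row1, col1)
    # integer weights proportional to the hypergeometric pmf
    weights = [math.comb(col1, k) * math.comb(n_total - col1, row1 - k) for k in range(lo, hi + 1)]
    denom = sum(weights)
    w_obs = weights[a - lo]
    if alternative == "two-sided":
        num = sum(w for w in weights if w <= w_obs)
    elif alternative == "greater":
        num = sum(weights[a - lo :])
    elif alternative == "less":
        num = sum(weights[: a - lo + 1])
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    p = float(min(Fraction(num, denom), Fraction(1)))
    return TestResult(float(oratio), p, "fisher_exact", n_total, True, odds_ratio=oratio)


def _concordance_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, np.ndarray, np.ndarray]:
    """Concordant/discordant pair counts plus row/column tie counts."""
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xs.size, ys.size), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    conc = disc = 0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            if table[i, j] == 0:
                continue
            conc += int(table[i, j]) * int(table[i + 1 :, j + 1 :].sum())
            disc += int(table[i, j]) * int(table[i + 1 :, :j].sum())
    return conc, disc, table.sum(axis=1), table.sum(axis=0)


def _tau_b_from_counts(conc, disc, row_t, col_t, n) -> float:
    n0 = n * (n - 1) // 2
    n1 = int((row_t * (row_t - 1) // 2).sum())
    n2 = int((col_t * (col_t - 1) // 2).sum())
    denom = math.sqrt(float(n0 - n1)) * math.sqrt(float(n0 - n2))
    if denom == 0:
        return math.nan
    return (conc - disc) / denom


def kendall_tau_b(x, y, exact_limit: int = 8) -> TestResult:
    """Kendall rank correlation with tie correction (tau-b).

    Pair counting runs on the contingency table of unique values, so heavily
    tied (e.g. ternary) vectors of any length are cheap. For
    ``n <= exact_limit`` the two-sided p enumerates all permutations of one
    vector (``P(|T| >= |t_obs|)``); above it, the normal approximation on
    ``C - D`` with the standard tie-corrected null variance.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    n = int(x.size)
    conc, disc, row_t, col_t, = _concordance_counts(x, y)
    tau = _tau_b_from_counts(conc, disc, row_t, col_t, n)
    if math.isnan(tau):
        return TestResult(math.nan, 1.0, "kendall_tau_b", n, True, degenerate=True)
    if n <= exact_limit:
        n_extreme = 0
        n_perms = 0
        target = abs(tau) - 1e-12
        for perm in itertools.permutations(y):
            c, d2, rt, ct = _concordance_counts(x, np.asarray(perm))
            t = _tau_b_from_counts(c, d2, rt, ct, n)
            n_perms += 1
            if abs(t) >= target:
                n_extreme += 1
        return TestResult(tau, n_extreme / n_perms, "kendall_tau_b", n, True)
    s = conc - disc
    rt = row_t.astype(float)
    ct = col_t.astype(float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = (rt * (rt - 1) * (2 * rt + 5)).sum()
    vu = (ct * (ct - 1) * (2 * ct + 5)).sum()
    v1 = (rt * (rt - 1)).sum() * (ct * (ct - 1)).sum() / (2.0 * n * (n - 1))
    v2 = (
        (rt * (rt - 1) * (rt - 2)).sum()
        * (ct * (ct - 1) * (ct - 2)).sum()
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    if var <= 0:
        return TestResult(tau, 1.0, "kendall_tau_b", n, False, degenerate=True)
    z = s / math.sqrt(var)
    p = float(min(1.0, 2 * _sps.norm.sf(abs(z))))
    return TestResult(tau, p, "kendall_tau_b", n, False)


def t_test_two_tailed(x, y) -> TestResult:
    """Two-sample Student t-test (pooled variance), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs n >= 2")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        t = 0.0 if x.mean() == y.mean() else math.copysign(math.inf, x.mean() - y.mean())
        return TestResult(t, 1.0 if t == 0 else 0.0, "t_test", nx + ny, False, degenerate=True)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = float(2 * _sps.t.sf(abs(t), df))
    return TestResult(float(t), p, "t_test", nx + ny, False)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, clipped to [0, 1]."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
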