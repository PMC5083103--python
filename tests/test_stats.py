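"""Exact-test kernel against brute-force enumeration oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from pairedspc import stats as st

rng = np.random.default_rng(20240917)


# ---------------------------------------------------------------- oracles


def oracle_signed_rank(diffs):
    """Two-sided exact p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    return float(min(Fraction(2 * min(n_le, n_ge), 2**n), Fraction(1)))


def oracle_rank_sum(x, y):
    """Two-sided exact p by enumerating all C(n, nx) group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:nx].sum()
    n_le = n_ge = n_tot = 0
    for combo in itertools.combinations(range(pooled.size), nx):
        w = ranks[list(combo)].sum()
        n_tot += 1
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    return float(min(Fraction(2 * min(n_le, n_ge), n_tot), Fraction(1)))


def oracle_fisher(a, b, c, d):
    """Two-sided Fisher p from exact rational hypergeometric probabilities."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, col1)
    lo, hi = max(0, col1 - (c + d)), min(row1, col1)
    probs = {
        k: Fraction(math.comb(row1, k) * math.comb(n - row1, col1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(min(sum(p for p in probs.values() if p <= p_obs), Fraction(1)))


def oracle_tau_pairs(x, y):
    """tau-b by direct O(n^2) pair counting."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx, sy = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
            if sx == 0 and sy == 0:
                tx += 1
                ty += 1
            elif sx == 0:
                tx += 1
            elif sy == 0:
                ty += 1
            elif sx == sy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt(n0 - tx - (conc + disc and 0)) if False else None
    nx_ties = n0 - conc - disc - ty
    ny_ties = n0 - conc - disc - tx
    denom = math.sqrt(nx_ties + conc + disc) * math.sqrt(ny_ties + conc + disc)
    if denom == 0:
        return math.nan
    return (conc - disc) / denom


def oracle_tau_exact_p(x, y):
    """Exact permutation two-sided p for tau-b."""
    t_obs = oracle_tau_pairs(x, y)
    n_extreme = n_tot = 0
    for perm in itertools.permutations(y):
        t = oracle_tau_pairs(x, perm)
        n_tot += 1
        if abs(t) >= abs(t_obs) - 1e-12:
            n_extreme += 1
    return n_extreme / n_tot


# ------------------------------------------------------------ example values


def test_signed_rank_all_positive_smallest_p():
    """n=5 uniform positives: the most extreme exact two-sided p is 2/32."""
    res = st.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
    assert res.exact
    assert res.p == pytest.approx(2 / 32)


def test_signed_rank_drops_zeros_and_flags_degenerate():
    res = st.wilcoxon_signed_rank([0.0, 0.0, 0.0])
    assert res.degenerate and res.p == 1.0 and res.n == 0


def test_rank_sum_complete_separation():
    """nA=nB=4 with complete separation: exact two-sided p = 2/70."""
    res = st.wilcoxon_rank_sum([1, 2, 3, 4], [10, 11, 12, 13])
    assert res.exact
    assert res.p == pytest.approx(2 / 70)


def test_rank_sum_identical_groups_p_one():
    res = st.wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
    assert res.p == 1.0


def test_fisher_odds_ratio_and_conventions():
    res = st.fisher_exact([[5, 5], [15, 75]])
    assert res.odds_ratio == pytest.approx((5 * 75) / (5 * 15))
    # identical row proportions -> p = 1
    assert st.fisher_exact([[10, 20], [5, 10]]).p == 1.0
    # zero off-diagonal cell -> infinite odds ratio
    assert st.fisher_exact([[5, 0], [3, 7]]).odds_ratio == math.inf
    with pytest.raises(ValueError):
        st.fisher_exact([[1, -1], [2, 3]])


def test_kendall_tau_perfect_and_reversed():
    x = [1, 2, 3, 4, 5, 6]
    assert st.kendall_tau_b(x, x).statistic == pytest.approx(1.0)
    assert st.kendall_tau_b(x, x[::-1]).statistic == pytest.approx(-1.0)


def test_kendall_tau_degenerate_constant():
    res = st.kendall_tau_b([1, 1, 1], [2, 3, 4])
    assert res.degenerate and res.p == 1.0 and math.isnan(res.statistic)


def test_t_test_textbook_case():
    res = st.t_test_two_tailed([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(-3.674, abs=5e-4)
    assert res.p == pytest.approx(0.0213, abs=5e-4)
    ident = st.t_test_two_tailed([1, 2, 3], [1, 2, 3])
    assert ident.statistic == 0.0 and ident.p == 1.0


def test_bh_fdr_hand_example():
    """p=(.01,.02,.03), m=3 -> all adjusted to 0.03 by step-up."""
    np.testing.assert_allclose(st.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(st.bh_fdr([1.0, 1.0]), [1.0, 1.0])
    np.testing.assert_allclose(st.bh_fdr([0.2]), [0.2])
    with pytest.raises(ValueError):
        st.bh_fdr([0.5, 1.5])


# ------------------------------------------------------- oracle equivalence


@pytest.mark.parametrize("trial", range(30))
def test_signed_rank_matches_enumeration(trial):
    n = int(rng.integers(3, 13))
    d = rng.integers(-5, 6, size=n).astype(float)
    if np.all(d == 0):
        d[0] = 1.0
    res = st.wilcoxon_signed_rank(d)
    assert res.exact
    assert res.p == oracle_signed_rank(d)


@pytest.mark.parametrize("trial", range(25))
def test_rank_sum_matches_enumeration(trial):
    nx = int(rng.integers(2, 8))
    ny = int(rng.integers(2, 8))
    x = rng.integers(0, 8, size=nx).astype(float)
    y = rng.integers(0, 8, size=ny).astype(float)
    res = st.wilcoxon_rank_sum(x, y)
    assert res.exact
    assert res.p == oracle_rank_sum(x, y)


@pytest.mark.parametrize("trial", range(40))
def test_fisher_matches_rational_enumeration(trial):
    a, b, c, d = (int(v) for v in rng.integers(0, 25, size=4))
    res = st.fisher_exact([[a, b], [c, d]])
    assert res.p == pytest.approx(oracle_fisher(a, b, c, d), abs=1e-12)
    ref = sps.fisher_exact([[a, b], [c, d]])
    assert res.p == pytest.approx(ref.pvalue, abs=1e-9)


@pytest.mark.parametrize("trial", range(12))
def test_tau_b_matches_permutation_enumeration(trial):
    n = int(rng.integers(4, 8))
    x = rng.integers(-1, 2, size=n).astype(float)
    y = rng.integers(-1, 2, size=n).astype(float)
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        x[0] += 1
        y[-1] += 1
    res = st.kendall_tau_b(x, y)
    assert res.exact
    assert res.statistic == pytest.approx(oracle_tau_pairs(x, y), abs=1e-12)
    assert res.p == pytest.approx(oracle_tau_exact_p(x, y), abs=1e-12)


@pytest.mark.parametrize("trial", range(10))
def test_tau_b_approx_matches_scipy_on_large_tied_vectors(trial):
    n = 300
    x = rng.integers(-1, 2, size=n).astype(float)
    y = rng.integers(-1, 2, size=n).astype(float)
    res = st.kendall_tau_b(x, y, exact_limit=8)
    ref = sps.kendalltau(x, y)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_t_test_matches_closed_form_on_random_inputs():
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(2, 10)))
        y = rng.normal(size=int(rng.integers(2, 10)))
        res = st.t_test_two_tailed(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)


# ------------------------------------------------------------- properties


def test_two_sided_p_invariant_to_label_swap():
    for _ in range(15):
        x = rng.normal(size=int(rng.integers(2, 7)))
        y = rng.normal(size=int(rng.integers(2, 7)))
        assert st.wilcoxon_rank_sum(x, y).p == pytest.approx(st.wilcoxon_rank_sum(y, x).p)
        assert st.t_test_two_tailed(x, y).p == pytest.approx(st.t_test_two_tailed(y, x).p)
    a, b, c, d = 3, 9, 7, 2
    assert st.fisher_exact([[a, b], [c, d]]).p == st.fisher_exact([[c, d], [a, b]]).p


def test_approx_paths_converge_to_exact_at_regime_boundary():
    """Normal approximations agree with enumeration near the exact cutoff."""
    worst = 0.0
    for _ in range(25):
        d = rng.normal(size=25)
        p_ex = st.wilcoxon_signed_rank(d, exact_limit=25).p
        p_ap = st.wilcoxon_signed_rank(d, exact_limit=5).p
        worst = max(worst, abs(p_ex - p_ap))
        x, y = rng.normal(size=10), rng.normal(size=10)
        p_ex = st.wilcoxon_rank_sum(x, y, exact_limit=20).p
        p_ap = st.wilcoxon_rank_sum(x, y, exact_limit=5).p
        worst = max(worst, abs(p_ex - p_ap))
    assert worst <= 0.01


def test_signed_rank_batch_equals_scalar_path():
    d = rng.normal(size=(50, 12))
    d[3, 4] = 0.0
    d[7, 1] = d[7, 5]  # force a tie in |differences|
    w, p = st.wilcoxon_signed_rank_batch(d)
    for i in range(d.shape[0]):
        res = st.wilcoxon_signed_rank(d[i])
        assert w[i] == pytest.approx(res.statistic)
        assert p[i] == pytest.approx(res.p)
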