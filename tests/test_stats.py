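"""Statistical primitives against brute-force oracles and closed forms."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as scipy_stats

from crossomics import stats
from crossomics.errors import StatisticalPreconditionError


# ---------------------------------------------------------------------------
# enumeration oracles (independent of the implementation under test)


def signed_rank_oracle_p(diffs):
    """Two-sided p by enumerating all 2^m sign patterns of |diffs|."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = scipy_stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.asarray(ws)
    lower = (ws <= w_obs + 1e-9).mean()
    upper = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lower, upper))


def rank_sum_oracle_p(x, y):
    """Two-sided p by enumerating all group labelings of the pooled values."""
    pooled = np.concatenate([x, y])
    ranks = scipy_stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    lower = (sums <= w_obs + 1e-9).mean()
    upper = (sums >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lower, upper))


# ---------------------------------------------------------------------------
# rank_average / spearman


@pytest.mark.parametrize(
    "values,expected",
    [
        ([10, 20, 30], [1, 2, 3]),
        ([5, 5], [1.5, 1.5]),
        ([3, 1, 3, 2], [3.5, 1, 3.5, 2]),
    ],
)
def test_rank_average_examples(values, expected):
    assert stats.rank_average(values).tolist() == expected


@given(st.lists(st.integers(-50, 50), min_size=1, max_size=40))
@settings(max_examples=100, deadline=None)
def test_rank_average_matches_scipy(values):
    np.testing.assert_allclose(
        stats.rank_average(values), scipy_stats.rankdata(values)
    )


def test_spearman_rho_monotone_extremes():
    assert stats.spearman_rho([1, 2, 3], [10, 20, 30]) == 1.0
    assert stats.spearman_rho([1, 2, 3], [3, 2, 1]) == -1.0


def test_spearman_rho_with_ties_equals_pearson_on_ranks():
    x, y = [1, 2, 2, 4], [1, 3, 2, 4]
    rx, ry = [1, 2.5, 2.5, 4], [1, 3, 2, 4]
    expected = np.corrcoef(rx, ry)[0, 1]
    assert stats.spearman_rho(x, y) == pytest.approx(expected)


def test_spearman_rho_constant_input_errors():
    with pytest.raises(StatisticalPreconditionError):
        stats.spearman_rho([1, 1, 1], [1, 2, 3])


@given(
    st.lists(st.floats(-100, 100), min_size=4, max_size=30, unique=True),
    st.randoms(use_true_random=False),
)
@settings(max_examples=50, deadline=None)
def test_spearman_matches_scipy(x, rand):
    y = list(x)
    rand.shuffle(y)
    got = stats.spearman(x, y)
    ref_rho, ref_p = scipy_stats.spearmanr(x, y)
    assert got.rho == pytest.approx(ref_rho, abs=1e-12)
    assert got.p_value == pytest.approx(ref_p, rel=1e-6)


def test_spearman_p_zero_rho_is_one():
    assert stats.spearman_p_from_rho(0.0, 20) == pytest.approx(1.0)


def test_spearman_p_perfect_rho_is_zero():
    assert stats.spearman_p_from_rho(1.0, 10) == 0.0
    assert stats.spearman_p_from_rho(-1.0, 10) == 0.0


def test_spearman_p_requires_four():
    with pytest.raises(StatisticalPreconditionError):
        stats.spearman_p_from_rho(0.5, 3)


def test_spearman_p_monotone_in_rho_and_n():
    rhos = np.linspace(0.05, 0.95, 10)
    ps = [stats.spearman_p_from_rho(r, 15) for r in rhos]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    ns = [5, 8, 12, 20, 40]
    pn = [stats.spearman_p_from_rho(0.4, n) for n in ns]
    assert all(a > b for a, b in zip(pn, pn[1:]))


def test_spearman_exact_permutation_small_n():
    # n=5, perfect monotone: only 2 of 120 permutations reach |rho|=1
    p = stats.spearman_p_from_rho(1.0, 5, exact=True)
    assert p == pytest.approx(2 / 120)


# ---------------------------------------------------------------------------
# wilcoxon signed-rank


def test_signed_rank_hand_cases():
    r = stats.wilcoxon_signed_rank([1, 2, 3])
    assert (r.statistic, r.p_value, r.method) == (6.0, 0.25, "exact")
    r = stats.wilcoxon_signed_rank([-1, -2, -3, -4])
    assert r.p_value == pytest.approx(0.125)
    assert r.method == "exact"


def test_signed_rank_zero_discard_leaves_too_few():
    with pytest.raises(StatisticalPreconditionError):
        stats.wilcoxon_signed_rank([0, 0, 1])


def test_signed_rank_all_zero_errors():
    with pytest.raises(StatisticalPreconditionError):
        stats.wilcoxon_signed_rank([0.0, 0.0, 0.0])


def test_signed_rank_paired_form_matches_diff_form():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [2.0, 1.5, 5.0, 4.5]
    a = stats.wilcoxon_signed_rank(x, y)
    b = stats.wilcoxon_signed_rank(np.subtract(y, x))
    assert a == b


@given(
    st.lists(
        st.integers(-40, 40).filter(lambda v: v != 0),
        min_size=3,
        max_size=8,
        unique_by=abs,
    )
)
@settings(max_examples=200, deadline=None)
def test_signed_rank_exact_equals_enumeration(diffs):
    got = stats.wilcoxon_signed_rank(diffs)
    assert got.method == "exact"
    assert got.p_value == pytest.approx(signed_rank_oracle_p(diffs))


@given(st.lists(st.integers(-30, 30), min_size=4, max_size=15))
@settings(max_examples=100, deadline=None)
def test_signed_rank_two_sided_symmetry(diffs):
    d = np.asarray(diffs, float)
    if (d != 0).sum() < 3:
        return
    a = stats.wilcoxon_signed_rank(d)
    b = stats.wilcoxon_signed_rank(-d)
    assert a.p_value == pytest.approx(b.p_value)


def test_signed_rank_approximation_tracks_scipy():
    rng = np.random.default_rng(0)
    d = rng.normal(0.3, 1.0, size=40)
    got = stats.wilcoxon_signed_rank(d)
    assert got.method == "normal_approx"
    ref = scipy_stats.wilcoxon(d, correction=True, method="approx")
    assert got.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# wilcoxon rank-sum


def test_rank_sum_hand_case():
    r = stats.wilcoxon_rank_sum([1, 2], [3, 4])
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(1 / 3)
    assert r.method == "exact"


def test_rank_sum_identical_groups_p_one():
    assert stats.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)


def test_rank_sum_empty_group_errors():
    with pytest.raises(StatisticalPreconditionError):
        stats.wilcoxon_rank_sum([1.0], [1.0, 2.0])


@given(
    st.lists(st.integers(0, 200), min_size=4, max_size=12, unique=True),
    st.integers(2, 10),
)
@settings(max_examples=200, deadline=None)
def test_rank_sum_exact_equals_enumeration(pool, cut):
    if not (2 <= cut <= len(pool) - 2):
        return
    x, y = pool[:cut], pool[cut:]
    got = stats.wilcoxon_rank_sum(x, y)
    assert got.method == "exact"
    assert got.p_value == pytest.approx(rank_sum_oracle_p(x, y))


def test_rank_sum_group_swap_symmetry(rng):
    x = rng.normal(size=30)
    y = rng.normal(0.5, 1, size=25)
    assert stats.wilcoxon_rank_sum(x, y).p_value == pytest.approx(
        stats.wilcoxon_rank_sum(y, x).p_value
    )


def test_rank_sum_approx_close_to_exact_subsample(rng):
    # shifted samples: approximation on the full data should be of the same
    # order as exact enumeration on a tie-free subsample
    x = np.round(rng.normal(0, 1, 50), 3)
    y = np.round(rng.normal(0.6, 1, 50), 3)
    full = stats.wilcoxon_rank_sum(x, y)
    assert full.method == "normal_approx"
    ref = scipy_stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True)
    assert full.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# paired t / Cohen's d


def test_paired_t_symmetric_differences_give_p_one():
    r = stats.paired_t([1, -1, 1, -1])
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_paired_t_zero_variance_errors():
    with pytest.raises(StatisticalPreconditionError):
        stats.paired_t([1.0, 1.0, 1.0])


def test_paired_t_matches_scipy(rng):
    x = rng.normal(size=15)
    y = x + rng.normal(0.4, 1, size=15)
    got = stats.paired_t(x, y)
    ref = scipy_stats.ttest_rel(y, x)
    assert got.statistic == pytest.approx(ref.statistic)
    assert got.p_value == pytest.approx(ref.pvalue)


def test_cohens_d_hand_case_and_scale_invariance():
    es = stats.cohens_d_paired([0.0, 2.0])
    assert es.d == pytest.approx(1 / math.sqrt(2))
    assert es.ci_low <= es.d <= es.ci_high
    a = stats.cohens_d_paired([1.0, 3.0, 2.0])
    b = stats.cohens_d_paired([10.0, 30.0, 20.0])
    assert a.d == pytest.approx(b.d)


def test_cohens_d_constant_differences_error():
    with pytest.raises(StatisticalPreconditionError):
        stats.cohens_d_paired([0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_oracle(p):
    """Definitional step-up: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        q[idx] = min(
            min(m * p[order[j]] / (j + 1) for j in range(pos, m)), 1.0
        )
    return q


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([1.0], [1.0]),
    ],
)
def test_bh_hand_cases(p, expected):
    np.testing.assert_allclose(stats.bh_fdr(p), expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        stats.bh_fdr([0.5, 1.5])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
@settings(max_examples=200, deadline=None)
def test_bh_matches_oracle_and_is_monotone(p):
    q = stats.bh_fdr(p)
    np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
    assert (q >= np.asarray(p) - 1e-12).all()
    assert (q <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=200)
    np.testing.assert_allclose(
        stats.bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
    )
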