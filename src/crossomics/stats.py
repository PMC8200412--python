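"""Statistical primitives for paired crossover-trial analysis.

Every primitive used by the downstream pipeline lives here and is written
out explicitly so each one can be checked against a brute-force oracle
(full enumeration of sign patterns or group labelings) or a closed form in
the test suite.  External libraries are used only for reference
distributions (Student t, standard normal), never for the rank machinery
or the enumeration itself.

Conventions
-----------
* All tests are two-sided; no one-sided mode is exposed.
* Zero differences in the signed-rank test are discarded before ranking
  (the classic Wilcoxon treatment).
* Exact null distributions are used when feasible: signed-rank up to
  ``m <= 25`` untied differences (rank-sum generating-function recursion),
  rank-sum up to ``n1 + n2 <= 12`` without ties (enumeration of group
  labelings).  Beyond that, normal approximations with tie and continuity
  corrections are used.
* Spearman p-values use the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``
  with ``n - 2`` degrees of freedom at all n; an exact permutation option
  exists for ``n <= 10``.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

from .errors import StatisticalPreconditionError

__all__ = [
    "TestResult",
    "CorrelationResult",
    "EffectSize",
    "rank_average",
    "spearman_rho",
    "spearman_p_from_rho",
    "spearman",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "paired_t",
    "cohens_d_paired",
    "bh_fdr",
]

# Exact-vs-approximation crossover points.  Chosen so that a tie-free
# 20-subject trial uses the exact signed-rank null.
SIGNED_RANK_EXACT_LIMIT = 25
RANK_SUM_EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test.

    ``statistic`` is W+ (sum of positive-difference ranks) for the
    signed-rank test, U for the rank-sum test, and t for the paired t-test.
    ``method`` records which null distribution produced the p-value.
    """

    statistic: float
    p_value: float
    n_effective: int
    method: str  # "exact" | "normal_approx" | "t_approx" | "degenerate"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| = {abs(self.rho)} exceeds 1")


@dataclass(frozen=True)
class EffectSize:
    """Paired Cohen's d with a normal-approximation confidence interval."""

    d: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def _as_clean_array(values: Sequence[float], name: str = "values") -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError(f"{name} must be a nonempty 1-d sequence")
    if np.isnan(a).any():
        raise ValueError(f"{name} contains missing values")
    return a


def rank_average(values: Sequence[float]) -> np.ndarray:
    """Average (midrank) 1-based ranks; tied values share their rank-span mean."""
    a = _as_clean_array(values)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(a.size, dtype=float)
    sorted_vals = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks."""
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise StatisticalPreconditionError("spearman_rho needs n >= 3")
    rx = rank_average(xa)
    ry = rank_average(ya)
    # perfectly monotone inputs give exactly +/-1, not a rounded float
    if np.array_equal(rx, ry) and np.unique(rx).size > 1:
        return 1.0
    if np.array_equal(rx, rx.size + 1 - ry) and np.unique(rx).size > 1:
        return -1.0
    rx -= rx.mean()
    ry -= ry.mean()
    sx = math.sqrt(float(rx @ rx))
    sy = math.sqrt(float(ry @ ry))
    if sx == 0.0:
        raise StatisticalPreconditionError("x is constant; rho undefined")
    if sy == 0.0:
        raise StatisticalPreconditionError("y is constant; rho undefined")
    rho = float(rx @ ry) / (sx * sy)
    return max(-1.0, min(1.0, rho))


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided permutation p-value for untied ranks (n <= 10)."""
    base = np.arange(1, n + 1, dtype=float)
    centred = base - base.mean()
    denom = float(centred @ centred)
    target = abs(rho) - 1e-12
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float(centred @ centred[list(perm)]) / denom
        if abs(r) >= target:
            hits += 1
        total += 1
    return hits / total


def spearman_p_from_rho(rho: float, n: int, exact: bool = False) -> float:
    """Two-sided p-value for a Spearman coefficient at sample size n.

    Default is the Student-t approximation ``t = rho*sqrt((n-2)/(1-rho^2))``
    on ``n - 2`` degrees of freedom.  With ``exact=True`` (n <= 10) the full
    permutation distribution over untied ranks is enumerated instead.
    """
    if n < 4:
        raise StatisticalPreconditionError("spearman p requires n >= 4")
    if abs(rho) > 1:
        raise ValueError("|rho| cannot exceed 1")
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        return _spearman_exact_p(rho, n)
    if abs(rho) >= 1.0:
        # Perfectly monotone input: the t statistic diverges.
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * special.stdtr(n - 2, -abs(t)))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman correlation with the t-approximation p-value."""
    rho = spearman_rho(x, y)
    n = len(np.asarray(x))
    return CorrelationResult(rho=rho, p_value=spearman_p_from_rho(rho, n), n=n)


@functools.lru_cache(maxsize=64)
def _signed_rank_counts_cached(m: int) -> np.ndarray:
    return _signed_rank_counts(m)


def _signed_rank_counts(m: int) -> np.ndarray:
    """Counts of W+ over all 2^m sign patterns for untied ranks 1..m.

    Generating-function recursion: product over r of (1 + x^r).  Counts fit
    exactly in float64 for m <= 25 (2^25 < 2^53).
    """
    max_sum = m * (m + 1) // 2
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in range(1, m + 1):
        counts[r:] += counts[: max_sum + 1 - r].copy()
    return counts


def _two_sided_from_counts(counts: np.ndarray, stat: float) -> float:
    total = counts.sum()
    k = int(round(stat))
    lower = counts[: k + 1].sum() / total
    upper = counts[k:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    exact_limit: int = SIGNED_RANK_EXACT_LIMIT,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test.

    Call with paired samples ``(x, y)`` — differences are ``y - x``
    (later minus earlier) — or with a single vector of differences.
    Zero differences are discarded; at least 3 nonzero differences are
    required.  Exact enumeration when the retained count is at most
    ``exact_limit`` and the absolute differences are tie-free; otherwise a
    normal approximation with tie and continuity corrections.
    """
    d = _paired_diffs(x, y)
    d = d[d != 0.0]
    m = d.size
    if m < 3:
        raise StatisticalPreconditionError(
            f"signed-rank test needs >= 3 nonzero differences, got {m}"
        )
    ranks = rank_average(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < m
    if m <= exact_limit and not has_ties:
        p = _two_sided_from_counts(_signed_rank_counts_cached(m), w_plus)
        return TestResult(w_plus, p, m, "exact")
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    # tie correction over groups of tied |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        return TestResult(w_plus, 1.0, m, "degenerate")
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
    p = float(special.ndtr(-abs(z)) * 2.0)
    return TestResult(w_plus, min(1.0, p), m, "normal_approx")


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = RANK_SUM_EXACT_LIMIT,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for two groups.

    Statistic is U for the first group.  Exact enumeration of all
    ``C(n1+n2, n1)`` group labelings when ``n1 + n2 <= exact_limit`` and the
    pooled values are tie-free; otherwise normal approximation with tie and
    continuity corrections.
    """
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    n1, n2 = xa.size, ya.size
    if n1 < 2 or n2 < 2:
        raise StatisticalPreconditionError("both groups need >= 2 observations")
    pooled = np.concatenate([xa, ya])
    ranks = rank_average(pooled)
    w_x = float(ranks[:n1].sum())
    u = w_x - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    has_ties = np.unique(pooled).size < n
    if n <= exact_limit and not has_ties:
        # enumerate rank sums of every n1-subset of ranks 1..n
        sums = np.array(
            [sum(c) for c in itertools.combinations(range(1, n + 1), n1)],
            dtype=float,
        )
        lower = float((sums <= w_x + 1e-9).mean())
        upper = float((sums >= w_x - 1e-9).mean())
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(u, p, n, "exact")
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, n, "degenerate")
    delta = w_x - mu
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
    p = float(special.ndtr(-abs(z)) * 2.0)
    return TestResult(u, min(1.0, p), n, "normal_approx")


def _paired_diffs(x: Sequence[float], y: Sequence[float] | None) -> np.ndarray:
    if y is None and hasattr(x, "x") and hasattr(x, "y"):
        x, y = x.x, x.y  # a PairedSeries-like object
    if y is None:
        return _as_clean_array(x, "differences")
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("paired samples must have equal length")
    return ya - xa


def paired_t(x: Sequence[float], y: Sequence[float] | None = None) -> TestResult:
    """Two-sided paired t-test on differences ``y - x`` (df = n - 1)."""
    d = _paired_diffs(x, y)
    n = d.size
    if n < 3:
        raise StatisticalPreconditionError("paired t-test needs >= 3 pairs")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise StatisticalPreconditionError("differences have zero variance")
    t = float(d.mean()) / (sd / math.sqrt(n))
    p = float(2.0 * special.stdtr(n - 1, -abs(t)))
    return TestResult(t, p, n, "t_approx")


def cohens_d_paired(
    x: Sequence[float], y: Sequence[float] | None = None, level: float = 0.95
) -> EffectSize:
    """Paired Cohen's d = mean(diff) / sd(diff) with sample (n-1) sd.

    The confidence interval is the normal approximation
    ``d +/- z * sqrt(1/n + d^2 / (2n))``.
    """
    d = _paired_diffs(x, y)
    n = d.size
    if n < 2:
        raise StatisticalPreconditionError("paired Cohen's d needs >= 2 pairs")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise StatisticalPreconditionError("differences have zero variance")
    eff = float(d.mean()) / sd
    z = float(-special.ndtri((1.0 - level) / 2.0))
    half = z * math.sqrt(1.0 / n + eff * eff / (2.0 * n))
    return EffectSize(eff, eff - half, eff + half, level)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the sorted p-values, capped at
    1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
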