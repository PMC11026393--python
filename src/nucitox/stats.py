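"""Nonparametric statistics on image-level summaries.

Implements the three procedures the downstream analyses rely on: Spearman
rank correlation, the Mann-Whitney U test, and Benjamini-Hochberg FDR
adjustment. They are written here from the rank definitions (rather than
delegating to a stats library) so the exact-p conventions — mid-rank ties,
enumeration-exact small-sample p-values, continuity correction — are pinned
down and testable against brute-force enumeration.

The intended analysis unit for group comparisons is the per-image mean, not
the individual cell: cells within one field are not independent, and testing
thousands of them against each other wildly overstates significance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as _spdist

__all__ = ["TestResult", "spearman_rho", "mann_whitney_u", "bh_fdr"]

#: largest per-group size at which Mann-Whitney uses enumeration-exact p
EXACT_LIMIT = 8

#: largest n at which Spearman p is computed by full permutation enumeration
SPEARMAN_EXACT_N = 10


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test: statistic (U or rho), two-sided p, sizes, mode."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    mode: str  # "exact", "asymptotic" or "undefined"

    @property
    def defined(self) -> bool:
        return self.mode != "undefined"


def midranks(x) -> np.ndarray:
    """Ranks 1..n with tied values sharing their average rank."""
    x = np.asarray(x, dtype=float)
    n = x.size
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sx = x[order]
    i = 0
    while i < n:
        j = i
        while j < n and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def spearman_rho(x, y) -> TestResult:
    """Spearman correlation: Pearson of mid-ranks, two-sided p.

    For n > SPEARMAN_EXACT_N the p-value uses the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df; for small n it is exact by
    enumerating all n! pairings of the rank vectors. A constant input vector
    makes rho undefined and is flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    n = x.size
    if n < 4:
        raise ValueError("spearman_rho requires n >= 4")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    rx, ry = midranks(x), midranks(y)
    rho = _pearson(rx, ry)
    if np.isnan(rho):
        return TestResult(np.nan, np.nan, n, n, "undefined")
    if n <= SPEARMAN_EXACT_N:
        p = _spearman_exact_p(rx, ry)
        mode = "exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(_spdist.t.sf(abs(t), df=n - 2))
        mode = "asymptotic"
    return TestResult(rho, min(p, 1.0), n, n, mode)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray) -> float:
    # rho under permutation is monotone in S = sum(rx * ry_perm) because the
    # rank multisets (hence means/SDs) are permutation-invariant.
    n = rx.size
    s_obs = float(rx @ ry)
    center = n * rx.mean() * ry.mean()
    d_obs = abs(s_obs - center) - 1e-9
    total = 0
    hits = 0
    chunk: list = []

    def flush(chunk):
        perm = np.asarray(chunk)
        s = perm @ rx
        return int((np.abs(s - center) >= d_obs).sum())

    for p in itertools.permutations(ry):
        chunk.append(p)
        if len(chunk) == 50_000:
            hits += flush(chunk)
            total += len(chunk)
            chunk = []
    if chunk:
        hits += flush(chunk)
        total += len(chunk)
    return hits / total


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts[u] over all C(n1+n2, n1) arrangements.

    Recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    """
    # dp[i][u] for j growing; implement as iterative table over (i, j)
    max_u = n1 * n2
    table = {(0, 0): np.array([1.0])}
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if (i, j) in table:
                continue
            acc = np.zeros(i * j + 1)
            if i > 0:
                prev = table[(i - 1, j)]
                acc[j : j + prev.size] += prev
            if j > 0:
                prev = table[(i, j - 1)]
                acc[: prev.size] += prev
            table[(i, j)] = acc
    counts = np.zeros(max_u + 1)
    got = table[(n1, n2)]
    counts[: got.size] = got
    return counts


def mann_whitney_u(group_a, group_b, two_sided: bool = True) -> TestResult:
    """Mann-Whitney U with mid-rank ties.

    Exact p by enumeration of the null U distribution when both groups have
    at most EXACT_LIMIT observations and the pooled sample is tie-free;
    otherwise normal approximation with tie correction and continuity
    correction. The reported statistic is U for group_a (number of (a, b)
    pairs with a > b, ties counting 1/2).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 3 or n2 < 3:
        raise ValueError("mann_whitney_u requires >= 3 observations per group")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values not allowed")
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = np.unique(pooled).size < pooled.size
    if n1 <= EXACT_LIMIT and n2 <= EXACT_LIMIT and not has_ties:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        u_small = min(u1, u2)
        p_small = counts[: int(round(u_small)) + 1].sum() / total
        p = min(1.0, 2.0 * p_small) if two_sided else counts[: int(round(u1)) + 1].sum() / total
        return TestResult(u1, p, n1, n2, "exact")
    # asymptotic with tie-corrected variance
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    if var <= 0:
        return TestResult(u1, 1.0, n1, n2, "asymptotic")
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    sf = float(_spdist.norm.sf(z))
    p = min(1.0, 2.0 * sf) if two_sided else float(_spdist.norm.sf((u1 - mu - 0.5) / np.sqrt(var)))
    return TestResult(u1, p, n1, n2, "asymptotic")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
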