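"""Statistical tests and corrections used throughout the pipeline.

Native implementations of the two-sided Wilcoxon rank-sum test (exact by
enumeration for small tie-free samples, tie-corrected normal approximation
with continuity correction otherwise), the Pearson chi-square test on 2x2
tables, the hypergeometric upper tail evaluated in log space, and the
Benjamini-Hochberg step-up FDR. scipy supplies only distribution functions
(normal and chi-square survival functions, log-gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import special, stats as sp_stats

from .exceptions import DegenerateTableError

#: largest combined sample size for which the exact rank-sum null is enumerated
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sp_stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation p-value when the pooled sample has at most
    ``EXACT_WILCOXON_MAX_N`` observations and no ties; otherwise the normal
    approximation with mid-ranks, tie-corrected variance and a continuity
    correction of 1/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    has_ties = len(np.unique(pooled)) < n
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        return _exact_rank_sum(pooled, nx, len(y))
    ranks = _midranks(pooled)
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = nx * len(y) / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return TestResult(statistic=w, p_value=1.0, method="wilcoxon-approx", n_x=nx, n_y=len(y))
    diff = w - mu
    # continuity correction shrinks |diff| toward zero by 1/2
    z = (diff - math.copysign(min(0.5, abs(diff)), diff)) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sp_stats.norm.sf(abs(z))))
    return TestResult(statistic=w, p_value=p, method="wilcoxon-approx", n_x=nx, n_y=len(y))


def _exact_rank_sum(pooled: np.ndarray, nx: int, ny: int) -> TestResult:
    ranks = sp_stats.rankdata(pooled, method="average")
    w_obs = float(ranks[:nx].sum())
    n = nx + ny
    mu = nx * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    total = 0
    extreme = 0
    all_ranks = np.arange(1, n + 1)
    for combo in combinations(range(n), nx):
        w = float(all_ranks[list(combo)].sum())
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            extreme += 1
    return TestResult(
        statistic=w_obs, p_value=extreme / total, method="wilcoxon-exact", n_x=nx, n_y=ny
    )


def chi_square_2x2(
    table: Sequence[Sequence[float]], yates: bool = False
) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 count table.

    Statistic n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), 1 degree of freedom.
    ``yates`` applies the continuity correction |ad - bc| -> |ad - bc| - n/2
    (floored at zero). A table with any empty margin raises
    :class:`DegenerateTableError`.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise DegenerateTableError(f"2x2 table has an empty margin: {table!r}")
    det = a * d - b * c
    if yates:
        det = max(0.0, abs(det) - n / 2.0)
    stat = n * det**2 / math.prod(margins)
    p = float(sp_stats.chi2.sf(stat, df=1))
    return TestResult(
        statistic=float(stat),
        p_value=p,
        method="chi2-yates" if yates else "chi2",
        n_x=int(a + b),
        n_y=int(c + d),
    )


def _log_binom(n: float, k: float) -> float:
    return float(special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1))


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n`` draws without replacement from a population
    of ``N`` containing ``K`` successes. The PMF terms are accumulated in log
    space, stable for population sizes in the tens of thousands.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    log_denom = _log_binom(N, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denom
        for i in range(k, min(K, n) + 1)
    ]
    return float(min(1.0, np.exp(special.logsumexp(log_terms))))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min over j >= i (sorted order) of m * p(j) / j, clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
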