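"""Exact nonparametric tests with small-sample null distributions.

Implements the four tests used throughout the study's figure legends —
Mann–Whitney U, Wilcoxon matched-pairs signed rank, two-sample
Kolmogorov–Smirnov, and the 2×2 Pearson chi-square — with *exact*
two-sided p-values for small samples.  The two-sided convention is
p = min(1, 2 × one-sided tail probability), which reproduces legend
p-values printed by common analysis software (e.g. U=0 with groups of
5 and 6 → p = 2/C(11,5) ≈ 0.004).

The exact Mann–Whitney null distribution is obtained by counting, for
every attainable U, the number of rank assignments that produce it
(a subset-sum dynamic programme over ranks — equivalent to full
enumeration of all C(m+n, m) labelings).  The exact Wilcoxon null
enumerates all 2^n sign patterns through a polynomial convolution over
the (mid-)ranks, which stays exact under ties in |differences|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.special import kolmogorov
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

from .traces import DegenerateTraceError, InputError

__all__ = [
    "TestResult",
    "mw_u_counts",
    "mw_p_from_u",
    "mann_whitney_exact",
    "wilcoxon_exact",
    "ks_two_sample",
    "chi2_2x2",
]

MW_EXACT_MAX_N = 30  # exact path when m + n <= 30 and no ties
WILCOXON_EXACT_MAX_N = 20
MC_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_two_sided: float
    exact: bool
    n_params: dict = field(default_factory=dict)


def mw_u_counts(m: int, n: int) -> np.ndarray:
    """Exact null distribution of the Mann–Whitney U statistic.

    Returns an integer array ``c`` of length ``m*n + 1`` where ``c[u]``
    is the number of the C(m+n, m) equally likely rank assignments of
    the first sample that yield U = u.  Computed by a dynamic programme
    over ranks (choose m of the ranks 1..m+n, track the rank sum).
    """
    if m < 1 or n < 1:
        raise InputError("group sizes must be >= 1")
    total = m + n
    max_sum = sum(range(total - m + 1, total + 1))
    # ways[k, s]: subsets of size k of ranks seen so far with rank-sum s
    ways = np.zeros((m + 1, max_sum + 1), dtype=np.int64)
    ways[0, 0] = 1
    for rank in range(1, total + 1):
        upper = min(rank, m)
        for k in range(upper, 0, -1):
            ways[k, rank:] += ways[k - 1, : max_sum + 1 - rank]
    min_sum = m * (m + 1) // 2
    counts = ways[m, min_sum : min_sum + m * n + 1].copy()  # U1 = R1 - m(m+1)/2
    assert counts.sum() == comb(total, m)
    return counts


def mw_p_from_u(u: float, m: int, n: int) -> float:
    """Exact two-sided p from an observed U = min(U1, U2).

    p = min(1, 2 × P(U1 ≤ u)) under the exact null distribution of U1
    (symmetric about mn/2).  ``u`` must be an attainable integer value;
    half-integer U (tied data) has no exact null here.
    """
    if not float(u).is_integer():
        raise InputError("half-integer U implies ties; exact p undefined")
    u = int(u)
    if not 0 <= u <= m * n:
        raise InputError(f"U must lie in [0, {m * n}]")
    counts = mw_u_counts(m, n)
    tail = counts[: u + 1].sum() / counts.sum()
    return min(1.0, 2.0 * float(tail))


def _mw_u1(x: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney_exact(
    x: np.ndarray, y: np.ndarray, mc_seed: int = 0
) -> TestResult:
    """Two-sided Mann–Whitney test with the exact small-sample null.

    The exact path (no ties, m+n ≤ 30) enumerates the null distribution
    of U; with ties, mid-ranks are used and the p-value comes from a
    seeded 10,000-draw Monte Carlo permutation of group labels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    m, n = x.size, y.size
    u1 = _mw_u1(x, y)
    u = min(u1, m * n - u1)
    ties = np.unique(np.concatenate([x, y])).size < m + n
    if not ties and m + n <= MW_EXACT_MAX_N:
        p = mw_p_from_u(u, m, n)
        exact = True
    else:
        rng = np.random.default_rng(mc_seed)
        pooled = np.concatenate([x, y])
        hits = 0
        for _ in range(MC_PERMUTATIONS):
            rng.shuffle(pooled)
            u1p = _mw_u1(pooled[:m], pooled[m:])
            if min(u1p, m * n - u1p) <= u:
                hits += 1
        p = min(1.0, 2.0 * (hits + 1) / (MC_PERMUTATIONS + 1))
        exact = False
    return TestResult(
        method="mann_whitney",
        statistic=u,
        p_two_sided=p,
        exact=exact,
        n_params={"m": m, "n": n},
    )


def _wilcoxon_null_counts(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of W+ over all 2^n sign patterns.

    Ranks may be mid-ranks (half-integers); everything is done on a
    doubled integer grid, so the enumeration stays exact under ties.
    Returns ``(support_doubled, counts)``.
    """
    doubled = np.round(2 * ranks).astype(int)
    max_sum = int(doubled.sum())
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: max_sum + 1 - r].copy()
    return np.arange(max_sum + 1), counts


def wilcoxon_exact(differences: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped before ranking (the convention of
    common analysis software).  For n ≤ 20 the p-value enumerates all
    2^n sign patterns exactly; beyond that, a normal approximation with
    continuity correction is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateTraceError("all differences are zero; test undefined")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= WILCOXON_EXACT_MAX_N:
        support2, counts = _wilcoxon_null_counts(ranks)
        tail = counts[support2 <= round(2 * w)].sum() / counts.sum()
        p = min(1.0, 2.0 * float(tail))
        exact = True
    else:
        mean = n * (n + 1) / 4.0
        # variance with tie correction over groups of equal |d|
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z = (w - mean + 0.5) / np.sqrt(var)
        from scipy.stats import norm

        p = min(1.0, 2.0 * float(norm.cdf(z)))
        exact = False
    return TestResult(
        method="wilcoxon_signed_rank",
        statistic=w,
        p_two_sided=p,
        exact=exact,
        n_params={"n": n},
    )


def ks_two_sample(x: np.ndarray, y: np.ndarray, exact: bool = False) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    D = sup |ECDF_x − ECDF_y| evaluated over the pooled sample.  The
    p-value is asymptotic (Kolmogorov distribution at √(mn/(m+n))·D) by
    default; ``exact=True`` requests the exact small-sample p (m·n ≤
    10⁴) from scipy's two-sample routine, while D is always computed
    here.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.abs(cdf_x - cdf_y).max())
    m, n = x.size, y.size
    if exact:
        if m * n > 10_000:
            raise InputError("exact KS p limited to m*n <= 10000")
        from scipy.stats import ks_2samp

        p = float(ks_2samp(x, y, method="exact").pvalue)
    else:
        en = np.sqrt(m * n / (m + n))
        p = float(np.clip(kolmogorov(en * d), 0.0, 1.0))
    return TestResult(
        method="ks_2samp",
        statistic=d,
        p_two_sided=p,
        exact=exact,
        n_params={"m": m, "n": n},
    )


def chi2_2x2(table: np.ndarray) -> TestResult:
    """Pearson chi-square on a 2×2 table, no continuity correction, 1 df."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InputError("table must be 2x2")
    if np.any(t < 0):
        raise InputError("counts must be nonnegative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    total = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise InputError("all marginals must be positive")
    expected = np.outer(row, col) / total
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(chi2_dist.sf(stat, df=1))
    return TestResult(
        method="chi2_2x2",
        statistic=stat,
        p_two_sided=p,
        exact=False,
        n_params={"df": 1, "n": int(total)},
    )
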