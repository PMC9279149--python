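"""Self-contained statistical primitives used throughout the pipeline.

The rank-sum test, Benjamini-Hochberg adjustment, two-part hurdle test,
hypergeometric tail and sign test are implemented here rather than wrapped,
so that every downstream threshold rule (FDR <= 0.05, |log2FC| >= 1.5, ...)
rests on code whose exact behaviour is pinned by the test suite against
brute-force enumeration.  scipy supplies only distribution functions
(normal/chi-square survival functions, hypergeometric pmf) and ranking.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np
from scipy.special import chdtrc, ndtr
from scipy.stats import hypergeom, rankdata

__all__ = [
    "rank_sum_test",
    "rank_sum_rows",
    "bh_fdr",
    "log2_fold_change",
    "fisher_exact_2x2",
    "hurdle_test",
    "hypergeometric_upper_tail",
    "sign_test",
    "bonferroni",
]

_EXACT_MAX = 10  # exact rank-sum enumeration up to this combined sample size


@lru_cache(maxsize=None)
def _ranksum_null_counts(m: int, n: int) -> tuple[np.ndarray, int]:
    """Exact null distribution of the rank sum of the first group.

    Returns ``counts[w]`` = number of ways to pick ``m`` of the ranks
    ``1..m+n`` summing to ``w``, and the total ``C(m+n, m)``.
    """
    total_ranks = m + n
    max_w = sum(range(total_ranks - m + 1, total_ranks + 1))
    # dp[k][w] = number of k-subsets of ranks seen so far with sum w
    dp = np.zeros((m + 1, max_w + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, total_ranks + 1):
        for k in range(min(r, m), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r > 0 else dp[k - 1]
    return dp[m], comb(total_ranks, m)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact enumeration of the null rank-sum distribution when the combined
    sample size is at most 10 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Identical constant
    samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    m, n = x.size, y.size
    ranks = rankdata(combined)
    w = ranks[:m].sum()
    has_ties = np.unique(combined).size < combined.size
    if m + n <= _EXACT_MAX and not has_ties:
        counts, total = _ranksum_null_counts(m, n)
        w_int = int(round(w))
        lower = counts[: w_int + 1].sum() / total
        upper = counts[w_int:].sum() / total
        return float(min(1.0, 2.0 * min(lower, upper)))
    return _ranksum_normal_p(w, m, n, combined[None, :])[0]


def _ranksum_normal_p(w, m: int, n: int, combined_rows: np.ndarray) -> np.ndarray:
    """Normal-approximation two-sided p for rank sums ``w`` (vectorised).

    ``combined_rows`` is the (rows x (m+n)) data matrix used for the tie
    correction; ``w`` is the per-row rank sum of the first group.
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    N = m + n
    mu = m * (N + 1) / 2.0
    tie_term = _tie_sums(combined_rows)
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    diff = w - mu
    # continuity correction of 0.5 toward the mean
    cc = np.where(diff > 0, -0.5, np.where(diff < 0, 0.5, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff + cc) / np.sqrt(var)
    p = 2.0 * (1.0 - ndtr(np.abs(z)))
    p = np.where(var <= 0, 1.0, np.minimum(p, 1.0))
    return p


def _tie_sums(rows: np.ndarray) -> np.ndarray:
    """Per-row sum of t^3 - t over tie groups."""
    rows = np.asarray(rows, dtype=float)
    r, n = rows.shape
    s = np.sort(rows, axis=1)
    new_group = np.ones_like(s, dtype=bool)
    new_group[:, 1:] = s[:, 1:] != s[:, :-1]
    gid = np.cumsum(new_group, axis=1) - 1  # 0-based group index within row
    flat = gid + (np.arange(r)[:, None] * n)
    counts = np.bincount(flat.ravel(), minlength=r * n).reshape(r, n)
    return (counts.astype(float) ** 3 - counts).sum(axis=1)


def rank_sum_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values (normal approximation).

    ``X`` is (features x n1), ``Y`` is (features x n2); each row is one
    feature tested across the two cell groups.  Uses the tie- and
    continuity-corrected normal approximation for every row (group sizes in
    real use are far beyond the exact-enumeration regime).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    m, n = X.shape[1], Y.shape[1]
    combined = np.concatenate([X, Y], axis=1)
    ranks = rankdata(combined, axis=1)
    w = ranks[:, :m].sum(axis=1)
    p = _ranksum_normal_p(w, m, n, combined)
    constant = np.ptp(combined, axis=1) == 0
    p[constant] = 1.0
    return p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def bonferroni(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    return np.minimum(p * p.size, 1.0)


def log2_fold_change(target_mean, background_mean, pseudocount: float = 1.0):
    """log2((target + c) / (background + c)) on the normalised scale."""
    t = np.asarray(target_mean, dtype=float)
    b = np.asarray(background_mean, dtype=float)
    out = np.log2((t + pseudocount) / (b + pseudocount))
    return float(out) if out.ndim == 0 else out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test p for the table [[a, b], [c, d]].

    Sums hypergeometric point probabilities no larger than the observed
    one (the 'minlike' convention used by R's fisher.test).
    """
    N = a + b + c + d
    if N == 0:
        return 1.0
    K = a + b  # first-row margin
    n = a + c  # first-column margin
    support = np.arange(max(0, n - (N - K)), min(K, n) + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    observed = hypergeom.pmf(a, N, K, n)
    return float(min(1.0, pmf[pmf <= observed * (1 + 1e-7)].sum()))


def hurdle_test(x, y) -> float:
    """Two-part (hurdle) test for zero-inflated expression values.

    Combines a Fisher exact test on detection (non-zero) proportions with a
    rank-sum test on the positive values via Fisher's method.  When one
    part is degenerate (detection identical in both groups, or too few
    positive values) the other part is returned alone; if both are
    degenerate, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    nx, ny = x.size, y.size
    dx, dy = int((x != 0).sum()), int((y != 0).sum())
    detection_degenerate = (dx == 0 and dy == 0) or (dx == nx and dy == ny)
    xp, yp = x[x != 0], y[y != 0]
    continuous_degenerate = xp.size < 1 or yp.size < 1
    if detection_degenerate and continuous_degenerate:
        return 1.0
    if detection_degenerate:
        return rank_sum_test(xp, yp)
    p_det = fisher_exact_2x2(dx, nx - dx, dy, ny - dy)
    if continuous_degenerate:
        return p_det
    p_cont = rank_sum_test(xp, yp)
    stat = -2.0 * (np.log(max(p_det, 1e-300)) + np.log(max(p_cont, 1e-300)))
    return float(chdtrc(4, stat))


def hypergeometric_upper_tail(overlap: int, universe: int, marked: int, drawn: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, marked, drawn)."""
    if overlap <= 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(overlap - 1, universe, marked, drawn)))


def sign_test(values) -> tuple[float, float]:
    """Exact two-sided binomial sign test on the signs of ``values``.

    Zeros are dropped.  Returns ``(p, fraction_negative)``; with no
    non-zero values, p = 1 and the fraction is NaN.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = v.size
    if n == 0:
        return 1.0, float("nan")
    k = int((v < 0).sum())
    # two-sided 'minlike' exact binomial p at theta = 1/2: by symmetry this
    # is the doubled smaller tail (with the midpoint counted once)
    pmf_k = comb(n, k) / 2.0**n
    total = 0.0
    for j in range(n + 1):
        pj = comb(n, j) / 2.0**n
        if pj <= pmf_k * (1 + 1e-12):
            total += pj
    return float(min(1.0, total)), k / n
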