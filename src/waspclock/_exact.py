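"""Exact null distributions for small-sample rank statistics.

Everything here is combinatorial: distributions are returned as integer (or
float) count/probability vectors indexed by the value of the statistic, and
are exact under within-series rank exchangeability (no ties). Ties are handled
upstream by Monte-Carlo permutation fallbacks.

The building block is the Mann-Whitney U null (counts of rank interleavings by
inversion number, i.e. Gaussian-binomial coefficients). Jonckheere-Terpstra
nulls follow by Harding's sequential convolution; the cyclic umbrella null is
obtained by conditioning on the peak- and trough-group rank sets, which renders
the two interior arms independent JT statistics.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "mann_whitney_counts",
    "jt_null_pmf",
    "umbrella_null_pmf",
    "rank_sum_exact_p",
]


@lru_cache(maxsize=None)
def _mw_counts_tuple(m: int, n: int) -> tuple[int, ...]:
    # Coefficients of the Gaussian binomial [m+n, n]_q: number of interleavings
    # of m X's and n Y's with U = u pairs (x, y), x before y ... i.e. the exact
    # null count of the Mann-Whitney statistic. Built by iterated multiplication
    # by (1 - q^{m+i}) and exact division by (1 - q^i).
    poly = [1]
    for i in range(1, n + 1):
        # multiply by (1 - q^{m+i})
        a = list(poly) + [0] * (m + i)
        for j, c in enumerate(poly):
            a[m + i + j] -= c
        # exact division by (1 - q^i):  s[j] = a[j] + s[j-i]
        s = [0] * (len(a) - i)
        for j in range(len(s)):
            s[j] = a[j] + (s[j - i] if j >= i else 0)
        poly = s
    assert sum(poly) == comb(m + n, n)
    return tuple(int(x) for x in poly)


def mann_whitney_counts(m: int, n: int) -> np.ndarray:
    """Exact null counts of U over the m*n + 1 possible values (no ties)."""
    if m == 0 or n == 0:
        return np.array([1], dtype=float)
    return np.array(_mw_counts_tuple(m, n), dtype=float)


@lru_cache(maxsize=None)
def _jt_counts(sizes: tuple[int, ...]) -> tuple[tuple[int, ...], int]:
    """Null counts of the Jonckheere-Terpstra statistic for ordered groups.

    JT = sum over group pairs (i < j) of #{x in group i < y in group j}.
    Harding's decomposition: JT is the independent sum over j of
    U(n_1 + ... + n_{j-1}, n_j), so the null is a convolution.
    Returns (counts, total), counts indexed by the statistic value from 0.
    """
    counts = np.array([1], dtype=object)
    total = 1
    acc = 0
    for sz in sizes:
        if acc > 0 and sz > 0:
            block = np.array(_mw_counts_tuple(acc, sz), dtype=object)
            counts = np.convolve(counts, block)
            total *= comb(acc + sz, sz)
        acc += sz
    return tuple(int(x) for x in counts), total


def jt_null_pmf(sizes: tuple[int, ...]) -> np.ndarray:
    """Exact JT null pmf for the given ordered group sizes (no ties)."""
    counts, total = _jt_counts(tuple(int(s) for s in sizes))
    return np.array(counts, dtype=float) / float(total)


def _cross_lt(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    return sum(1 for x in a for y in b if x < y)


@lru_cache(maxsize=None)
def _endpoint_hist(k: int, g: int) -> tuple[tuple[int, ...], int]:
    """Distribution of C = 2*U(T,P) + u(T, rest) + u(rest, P) over uniform
    choices of disjoint trough set T and peak set P (each of size g) from
    the k*g ranks. Returned as (counts by value of C, total)."""
    n = k * g
    ranks = tuple(range(n))
    max_c = 2 * g * g + 2 * g * (n - 2 * g)
    hist = [0] * (max_c + 1)
    total = 0
    for T in combinations(ranks, g):
        rest0 = tuple(x for x in ranks if x not in T)
        for P in combinations(rest0, g):
            rest = tuple(x for x in rest0 if x not in P)
            c = 2 * _cross_lt(T, P) + _cross_lt(T, rest) + _cross_lt(rest, P)
            hist[c] += 1
            total += 1
    return tuple(hist), total


@lru_cache(maxsize=None)
def umbrella_null_pmf(k: int, g: int, rising_len: int) -> np.ndarray:
    """Exact null pmf of the cyclic umbrella statistic.

    k phase groups of g observations each; the umbrella shape has a rising arm
    of ``rising_len`` steps from the trough group to the peak group (cyclically)
    and a falling arm of k - rising_len steps back. The statistic is

        S = sum over ordered rising-arm group pairs (u before v) of
            #{y_i < y_j : i in u, j in v}
          + sum over ordered falling-arm group pairs (u before v) of
            #{y_i > y_j : i in u, j in v}

    Conditioning on the rank sets of the trough and peak groups, S splits into
    a fixed cross term C plus two independent interior JT statistics, so the
    exact null is the convolution hist(C) * JT(r-1 groups) * JT(f-1 groups).
    Valid for tie-free data.
    """
    r = rising_len
    f = k - r
    if not (1 <= r <= k - 1):
        raise ValueError("rising_len must be between 1 and k-1")
    hist, total = _endpoint_hist(k, g)
    pmf = np.array(hist, dtype=float) / total
    for interior in (r - 1, f - 1):
        if interior > 0:
            pmf = np.convolve(pmf, jt_null_pmf((g,) * interior))
    return pmf


def sf_from_pmf(pmf: np.ndarray, value: float) -> float:
    """P(X >= value) for a pmf indexed from 0 (value may be fractional)."""
    idx = int(np.ceil(value - 1e-9))
    if idx <= 0:
        return 1.0
    if idx >= len(pmf):
        return 0.0
    return float(pmf[idx:].sum())


def rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Wilcoxon rank-sum p by enumeration (ties allowed).

    Enumerates all C(n1+n2, n1) assignments of the pooled values to the first
    group and doubles the smaller one-sided tail of the Mann-Whitney statistic
    (with 0.5 credit for ties), capping at 1. Intended for n1, n2 <= ~10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)

    def u_stat(ix: tuple[int, ...]) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[list(ix)] = True
        a = pooled[mask]
        b = pooled[~mask]
        lt = (a[:, None] < b[None, :]).sum()
        eq = (a[:, None] == b[None, :]).sum()
        return float(lt) + 0.5 * float(eq)

    u_obs = u_stat(tuple(range(n1)))
    us = np.array([u_stat(ix) for ix in combinations(range(n), n1)])
    p_lo = float((us <= u_obs + 1e-9).mean())
    p_hi = float((us >= u_obs - 1e-9).mean())
    return min(1.0, 2.0 * min(p_lo, p_hi))
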