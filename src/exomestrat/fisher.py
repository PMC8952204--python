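"""Two-sided Fisher exact test for 2x2 allele-count tables.

The allelic association test compares alternate-allele counts between two
groups of diploid individuals.  With the table

        alt   ref
    A    a     b        (a + b = 2 x non-missing samples in A)
    B    c     d

and margins fixed, the count ``a`` follows a hypergeometric distribution.
The two-sided p-value is the minimum-likelihood rule used by PLINK and R:
the sum of hypergeometric probabilities of all tables with the same margins
whose probability does not exceed that of the observed table (no mid-p).

A single-table interface is provided, but the workhorse is a vectorized,
margin-cached computation: the label-permutation stage recomputes on the
order of 10^7 p-values over tables that share margins, so per-margin
p-value lookup tables are built once (O(support log support)) and reused.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

# Relative slack when comparing hypergeometric probabilities, matching the
# convention of R's fisher.test: guards against floating-point noise around
# exact probability ties.
_REL_TOL = 1e-7

# (N, K, n1) -> (a_min, pvals); shared process-wide, bounded in practice by
# the distinct margins seen in one scan.
_MARGIN_CACHE: dict[tuple[int, int, int], tuple[int, np.ndarray]] = {}
_MARGIN_CACHE_MAX = 200_000


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def pvalues_for_margins(N: int, K: int, n1: int) -> tuple[int, np.ndarray]:
    """P-value lookup table for all tables with the given margins.

    Parameters
    ----------
    N : total allele count (all four cells).
    K : total alternate-allele count (first column margin).
    n1 : allele count in group A (first row margin).

    Returns
    -------
    (a_min, pvals) : ``pvals[a - a_min]`` is the two-sided p-value of the
    table with ``a`` alternate alleles in group A; ``a`` ranges over the
    hypergeometric support ``[max(0, K - (N - n1)), min(n1, K)]``.
    """
    if not (0 <= K <= N and 0 <= n1 <= N):
        raise ValueError(f"inconsistent margins N={N}, K={K}, n1={n1}")
    key = (N, K, n1)
    hit = _MARGIN_CACHE.get(key)
    if hit is not None:
        return hit
    a_min = max(0, K - (N - n1))
    a_max = min(n1, K)
    a = np.arange(a_min, a_max + 1)
    pmf = np.exp(_log_comb(K, a) + _log_comb(N - K, n1 - a) - _log_comb(N, n1))
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + _REL_TOL), side="right")
    pvals = np.minimum(csum[idx - 1], 1.0)
    if len(_MARGIN_CACHE) >= _MARGIN_CACHE_MAX:
        _MARGIN_CACHE.clear()
    _MARGIN_CACHE[key] = (a_min, pvals)
    return a_min, pvals


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of the 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    if N == 0:
        return 1.0
    a_min, pvals = pvalues_for_margins(N, a + c, a + b)
    return float(pvals[a - a_min])


def fisher_two_sided_many(a: np.ndarray, n1: np.ndarray, K: int, N: int) -> np.ndarray:
    """Vectorized two-sided Fisher p for tables sharing column total and grand total.

    ``a`` and ``n1`` are same-length integer arrays of group-A alt counts and
    group-A allele totals; ``K`` and ``N`` are the shared alt-allele and grand
    totals.  This is the permutation-scan case: shuffling labels never changes
    a variant's pooled counts, only how they split between the groups.
    """
    a = np.asarray(a, dtype=np.int64)
    n1 = np.asarray(n1, dtype=np.int64)
    out = np.empty(a.shape, dtype=np.float64)
    for n1_val in np.unique(n1):
        mask = n1 == n1_val
        a_min, pvals = pvalues_for_margins(N, K, int(n1_val))
        out[mask] = pvals[a[mask] - a_min]
    return out
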