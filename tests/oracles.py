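"""Independent oracles used to validate the package's statistics.

These deliberately avoid the package's own computational paths: the Fisher
oracle works in exact integer arithmetic over the full hypergeometric
support, and the power oracle enumerates the joint binomial outcome grid
using scipy's own fisher_exact for the rejection rule.
"""

from fractions import Fraction
from math import comb

from scipy.stats import binom, fisher_exact


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p (minimum-likelihood rule) by exact rational enumeration."""
    n1, K, N = a + b, a + c, a + b + c + d
    if N == 0:
        return 1.0
    a_min, a_max = max(0, K - (N - n1)), min(n1, K)
    weights = {x: comb(K, x) * comb(N - K, n1 - x) for x in range(a_min, a_max + 1)}
    obs = weights[a]
    total = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(total, comb(N, n1)))


def fisher_pvalues_for_margins_exact(N: int, K: int, n1: int):
    """(a_min, [p(a) for a in support]) by exact rational enumeration."""
    a_min, a_max = max(0, K - (N - n1)), min(n1, K)
    weights = [comb(K, x) * comb(N - K, n1 - x) for x in range(a_min, a_max + 1)]
    denom = comb(N, n1)
    pvals = [
        float(Fraction(sum(v for v in weights if v <= w), denom)) for w in weights
    ]
    return a_min, pvals


def exact_fisher_power(p1: float, p2: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided allelic Fisher test at 2n alleles per group.

    Sums P(reject) over the full joint grid of the two binomial allele
    counts; feasible for 2n <= ~25.
    """
    m = 2 * n_per_group
    pmf1 = [binom.pmf(k, m, p1) for k in range(m + 1)]
    pmf2 = [binom.pmf(k, m, p2) for k in range(m + 1)]
    power = 0.0
    for k1 in range(m + 1):
        for k2 in range(m + 1):
            p = fisher_exact([[k1, m - k1], [k2, m - k2]])[1]
            if p <= alpha:
                power += pmf1[k1] * pmf2[k2]
    return power


def permutation_null_exact(dosages, missing, n_a):
    """Exact permutation distribution of the allelic Fisher p for one variant.

    Enumerates every assignment of ``n_a`` of the samples to group A
    (itertools combinations) and returns the sorted tuple of p-values, one
    per assignment, computed with scipy's fisher_exact.
    """
    from itertools import combinations

    n = len(dosages)
    ps = []
    for group_a in combinations(range(n), n_a):
        in_a = set(group_a)
        a = n1 = c = n2 = 0
        for i in range(n):
            if missing[i]:
                continue
            if i in in_a:
                a += dosages[i]
                n1 += 2
            else:
                c += dosages[i]
                n2 += 2
        ps.append(fisher_exact([[a, n1 - a], [c, n2 - c]])[1])
    return sorted(ps)
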