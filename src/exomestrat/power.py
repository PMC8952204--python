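"""Simulation-based power of the two-group allelic Fisher exact test.

Per simulation, each group's alternate-allele count is drawn as
``Binomial(2 n, p)`` — allele-level sampling, equivalent in distribution to
per-sample Hardy–Weinberg genotypes — and the two-sided Fisher exact test
is applied to the resulting 2x2 table.  Power is the fraction of
simulations rejecting at ``alpha``, with the binomial standard error
``sqrt(power (1 - power) / n_sim)``.

The default sample-size grid (18, 50, 100, 500, 1000, 10000 per group)
spans the study design's group size up to biobank scale; raw per-size
estimates are reported without monotone smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fisher

DEFAULT_SIZES = (18, 50, 100, 500, 1000, 10_000)


@dataclass(frozen=True)
class PowerCurve:
    p1: float
    p2: float
    alpha: float
    sizes: tuple[int, ...]
    power: tuple[float, ...]
    se: tuple[float, ...]
    n_sim: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p1": self.p1,
                "p2": self.p2,
                "n_per_group": self.sizes,
                "alpha": self.alpha,
                "n_sim": self.n_sim,
                "power": self.power,
                "se": self.se,
            }
        )


def fisher_power(
    p1: float,
    p2: float,
    n_per_group: int,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Estimated power and its binomial SE at one per-group sample size."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("allele frequencies must lie in [0, 1]")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    m = 2 * n_per_group
    rng = np.random.default_rng(seed)
    k1 = rng.binomial(m, p1, size=n_sim)
    k2 = rng.binomial(m, p2, size=n_sim)
    # Tables share row margins (m, m); group by the column margin K = k1 + k2
    # so each distinct K costs one hypergeometric lookup-table build.
    K = k1 + k2
    pvals = np.empty(n_sim, dtype=np.float64)
    N = 2 * m
    for K_val in np.unique(K):
        mask = K == K_val
        a_min, lut = fisher.pvalues_for_margins(N, int(K_val), m)
        pvals[mask] = lut[k1[mask] - a_min]
    power = float((pvals <= alpha).mean())
    se = float(np.sqrt(power * (1.0 - power) / n_sim))
    return power, se


def power_curve(
    p1: float,
    p2: float,
    sizes=DEFAULT_SIZES,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int = 0,
) -> PowerCurve:
    """Power across a strictly increasing per-group sample-size grid."""
    sizes = tuple(int(s) for s in sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    powers, ses = [], []
    for i, n in enumerate(sizes):
        pw, se = fisher_power(p1, p2, n, alpha=alpha, n_sim=n_sim, seed=seed + i)
        powers.append(pw)
        ses.append(se)
    return PowerCurve(
        p1=p1, p2=p2, alpha=alpha, sizes=sizes,
        power=tuple(powers), se=tuple(ses), n_sim=n_sim, seed=seed,
    )
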