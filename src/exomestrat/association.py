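"""Pairwise allelic Fisher scan and allele-frequency profile assignment.

Each scan compares two groups (e.g. V vs K) at every variant that passes the
per-comparison call-rate filter, using the allelic 2x2 table — two alleles
per non-missing diploid genotype — and a two-sided Fisher exact test.  The
"profile" notation marks which group carries the strictly higher
alternate-allele frequency: ``V+K-`` means higher in Vata than Kapha.  Exact
frequency ties get a tie marker (``V=K=``) and are excluded from profile
replication, which requires a strict direction.

No multiple-testing correction is applied here by design: nominal p <= alpha
hits are subsequently filtered by the label-permutation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fisher
from .io import CohortDesign, GenotypeMatrix, filter_by_call_rate

#: The three constitution-group comparisons.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (("V", "P"), ("P", "K"), ("V", "K"))

SCAN_COLUMNS = [
    "variant_id", "gene", "pair", "a", "b", "c", "d",
    "freq_a", "freq_b", "p", "profile",
]


@dataclass(frozen=True)
class AllelicTable:
    """Allele counts for one variant: (alt, ref) in group A, then group B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")


def pair_label(pair) -> str:
    return f"{pair[0]}-{pair[1]}"


def allelic_counts(
    matrix: GenotypeMatrix, variant_index: int, group_a, group_b
) -> AllelicTable:
    """Count alleles (2 per non-missing diploid) for a group pair at a variant."""
    table = []
    for grp in (group_a, group_b):
        col = matrix.genotypes[matrix.sample_index(grp), variant_index]
        nm = col >= 0
        n_alleles = 2 * int(nm.sum())
        if n_alleles == 0:
            raise ValueError(f"no non-missing genotypes at variant {variant_index}")
        alt = int(col[nm].sum())
        table.extend([alt, n_alleles - alt])
    return AllelicTable(*table)


def fisher_two_sided(table: AllelicTable) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood rule, no mid-p)."""
    return fisher.fisher_two_sided(table.a, table.b, table.c, table.d)


def assign_profile(freq_a: float, freq_b: float, labels) -> str:
    """Profile label: '+' on the group with the strictly higher alt frequency."""
    ga, gb = labels
    if np.isnan(freq_a) or np.isnan(freq_b):
        raise ValueError("profile requires both frequencies defined")
    if freq_a > freq_b:
        return f"{ga}+{gb}-"
    if freq_b > freq_a:
        return f"{ga}-{gb}+"
    return f"{ga}={gb}="


def is_tie(profile: str) -> bool:
    return profile.endswith("=")


def scan_pair(
    matrix: GenotypeMatrix,
    design: CohortDesign,
    pair,
    cohort: str | None = None,
    call_rate_threshold: float = 0.5,
) -> pd.DataFrame:
    """Allelic Fisher scan of one group pair.

    Applies the call-rate filter over the union of the pair's samples, then
    returns one row per surviving variant with the allelic table, the two
    alternate-allele frequencies, the two-sided Fisher p and the profile.
    Variants with zero non-missing genotypes in either group (possible even
    at a 50% union call rate) are dropped.
    """
    ga, gb = pair
    samples_a = design.samples(cohort=cohort, group=ga)
    samples_b = design.samples(cohort=cohort, group=gb)
    if not samples_a or not samples_b:
        raise ValueError(f"no samples for pair {pair} (cohort={cohort!r})")
    kept = filter_by_call_rate(matrix, samples_a + samples_b, call_rate_threshold)

    ia, ib = matrix.sample_index(samples_a), matrix.sample_index(samples_b)
    GA = matrix.genotypes[ia][:, kept].astype(np.int64)
    GB = matrix.genotypes[ib][:, kept].astype(np.int64)
    a = np.where(GA >= 0, GA, 0).sum(axis=0)
    c = np.where(GB >= 0, GB, 0).sum(axis=0)
    n1 = 2 * (GA >= 0).sum(axis=0)
    n2 = 2 * (GB >= 0).sum(axis=0)
    ok = (n1 > 0) & (n2 > 0)

    kept, a, c, n1, n2 = kept[ok], a[ok], c[ok], n1[ok], n2[ok]
    b, d = n1 - a, n2 - c
    freq_a, freq_b = a / n1, c / n2
    p = np.array(
        [
            fisher.fisher_two_sided(int(ai), int(bi), int(ci), int(di))
            for ai, bi, ci, di in zip(a, b, c, d)
        ]
    )
    label = pair_label(pair)
    profiles = [assign_profile(fa, fb, pair) for fa, fb in zip(freq_a, freq_b)]
    return pd.DataFrame(
        {
            "variant_id": [matrix.variants[i].id for i in kept],
            "gene": [matrix.variants[i].gene for i in kept],
            "pair": label,
            "a": a, "b": b, "c": c, "d": d,
            "freq_a": freq_a, "freq_b": freq_b,
            "p": p,
            "profile": profiles,
        },
        index=pd.Index(kept, name="variant_index"),
    )


def pairwise_scan(
    matrix: GenotypeMatrix,
    design: CohortDesign,
    pairs=DEFAULT_PAIRS,
    cohort: str | None = None,
    call_rate_threshold: float = 0.5,
) -> pd.DataFrame:
    """Run scan_pair for each group pair; rows carry their pair label."""
    frames = [
        scan_pair(matrix, design, pair, cohort=cohort, call_rate_threshold=call_rate_threshold)
        for pair in pairs
    ]
    return pd.concat(frames).reset_index()
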