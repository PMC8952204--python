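"""Cross-cohort replication at three levels, and group-vs-control contrasts.

Replication of the differentiating sets of two independently analyzed
cohorts is assessed at:

1. gene level — gene symbols present in both cohorts' retained sets;
2. variant level — identical variant ids retained in both (by default in
   any pair; ``same_pair=True`` demands retention for the same comparison);
3. profile level — identical variants retained for the same group pair with
   the identical directional profile in both cohorts ("replicated profile
   SNPs").  Frequency ties never match.

Each group can additionally be contrasted against the background control
(V vs C, P vs C, K vs C) within one cohort — the controls are an
unstratified mixture of constitution types, so their allele frequency may
differ between cohorts even where the group profile replicates exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fisher
from .association import allelic_counts, assign_profile, is_tie, pair_label
from .io import CohortDesign, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReplicationReport:
    level1_genes: set[str]
    level2_ids: set[str]
    level3: pd.DataFrame  # variant_id, gene, pair, profile
    detail: pd.DataFrame  # per (variant, pair): profiles per cohort, match flag

    @property
    def level3_ids(self) -> set[str]:
        return set(self.level3["variant_id"])

    def check_containment(self) -> None:
        """Assert the nesting level3 ids <= level2 ids."""
        if not self.level3_ids <= self.level2_ids:
            raise AssertionError("level-3 set must be contained in level-2 set")


def replicate(
    set_a: pd.DataFrame, set_b: pd.DataFrame, same_pair: bool = False
) -> ReplicationReport:
    """Three-level replication of two cohorts' retained association results.

    Inputs are association-result frames (``scan_pair``/``pairwise_scan``
    rows) restricted to each cohort's retained variants; both cohorts must
    have been analyzed with the same pair definitions.  Variants without a
    gene annotation are excluded from level 1 only.
    """
    cols = ["variant_id", "gene", "pair", "profile"]
    A, B = set_a[cols].drop_duplicates(), set_b[cols].drop_duplicates()

    if same_pair:
        shared = pd.merge(A[["variant_id", "pair"]], B[["variant_id", "pair"]])
        level2_ids = set(shared["variant_id"])
    else:
        level2_ids = set(A["variant_id"]) & set(B["variant_id"])

    for frame, name in ((A, "A"), (B, "B")):
        n_missing = frame["gene"].isna().sum()
        if n_missing:
            logger.info("cohort %s: %d retained rows lack gene annotation", name, n_missing)
    level1_genes = set(A["gene"].dropna()) & set(B["gene"].dropna())

    detail = pd.merge(A, B, on=["variant_id", "pair"], suffixes=("_a", "_b"), how="inner")
    detail["match"] = (
        (detail["profile_a"] == detail["profile_b"])
        & ~detail["profile_a"].map(is_tie)
        & detail["variant_id"].isin(level2_ids)
    )
    level3 = (
        detail.loc[detail["match"], ["variant_id", "gene_a", "pair", "profile_a"]]
        .rename(columns={"gene_a": "gene", "profile_a": "profile"})
        .reset_index(drop=True)
    )
    return ReplicationReport(
        level1_genes=level1_genes, level2_ids=level2_ids, level3=level3, detail=detail
    )


def background_contrast(
    matrix: GenotypeMatrix,
    design: CohortDesign,
    group: str,
    snp_ids,
    cohort: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Allelic Fisher test of one group against the background control C.

    Restricted to the listed variant ids (the replicated-profile set in the
    standard workflow); returns one row per variant with the 2x2 counts,
    both frequencies, p and the significance flag at ``alpha``.
    """
    snp_ids = list(snp_ids)
    vidx = matrix.variant_index_by_id(snp_ids)
    grp = design.samples(cohort=cohort, group=group)
    ctrl = design.samples(cohort=cohort, group="C")
    if not ctrl:
        raise ValueError(f"no control (C) samples in cohort {cohort!r}")
    rows = []
    for vid, vi in zip(snp_ids, vidx):
        t = allelic_counts(matrix, int(vi), grp, ctrl)
        p = fisher.fisher_two_sided(t.a, t.b, t.c, t.d)
        fa, fb = t.a / (t.a + t.b), t.c / (t.c + t.d)
        rows.append(
            {
                "variant_id": vid,
                "gene": matrix.variants[vi].gene,
                "pair": pair_label((group, "C")),
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "freq_group": fa, "freq_control": fb,
                "p": p,
                "profile": assign_profile(fa, fb, (group, "C")),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def background_contrasts_all(
    matrix: GenotypeMatrix,
    design: CohortDesign,
    snp_ids,
    cohort: str | None = None,
    groups=("V", "P", "K"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group-vs-control contrasts for each constitution group, concatenated."""
    frames = [
        background_contrast(matrix, design, g, snp_ids, cohort=cohort, alpha=alpha)
        for g in groups
    ]
    return pd.concat(frames, ignore_index=True)
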