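"""Synthetic two-cohort stratified genotype data with planted group differences.

The generator emulates the study design the pipeline was built for: two
cohorts, each with 18 samples per group for the four groups V, P, K and C,
and 10^4–10^5 biallelic exonic variants.  Genotypes are drawn under
Hardy–Weinberg equilibrium at group-specific allele frequencies —
``Binomial(2, f_group)`` per sample — which matches the allelic test's
implicit treatment of alleles as independent draws.  Variants are simulated
independently (no linkage disequilibrium), a deliberate simplification:
every downstream method treats SNPs marginally.

A configurable fraction of variants is "planted" with a true frequency
difference (f_high vs f_low) on a target group pair; the remaining groups
sit at the mean of the two so the pooled frequency stays stable.  For a
replication pair of cohorts, planted variants share the same direction in
both cohorts while the background-control (C) frequency is redrawn per
cohort, mimicking control populations that are heterogeneous mixtures of
the constitution types.

A synthetic risk-allele catalog with the GWAS-catalog column layout
(SNP id, trait, parent term, risk allele, reported RAF) can be generated
against any simulated matrix so that catalog mapping, enrichment and risk
stratification are exercisable end to end without external resources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GROUPS, CohortDesign, GenotypeMatrix, Variant

PARENT_TERMS = (
    "Body measurement",
    "Metabolic disorder",
    "Hematological measurement",
    "Lipid or lipoprotein measurement",
    "Neurological disorder",
    "Immune system disorder",
    "Liver enzyme measurement",
    "Cardiovascular disease",
    "Inflammatory measurement",
    "Digestive system disorder",
    "Psychological trait",
    "Cancer",
    "Response to drug",
    "Skin disorder",
    "Respiratory disease",
    "Biological process",
    "Other measurement",
)


@dataclass(frozen=True)
class PlantedEffect:
    """A true between-group frequency difference at a planted variant."""

    pair: tuple[str, str] = ("V", "K")
    f_high: float = 0.8
    f_low: float = 0.2

    def __post_init__(self):
        if not (0.0 <= self.f_low < self.f_high <= 1.0):
            raise ValueError("require 0 <= f_low < f_high <= 1")
        if self.pair[0] not in GROUPS or self.pair[1] not in GROUPS:
            raise ValueError(f"pair groups must be in {GROUPS}")


@dataclass(frozen=True)
class SimulationConfig:
    n_per_group: int = 18
    n_variants: int = 10_000
    frac_planted: float = 0.01
    effects: tuple[PlantedEffect, ...] = (PlantedEffect(),)
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.02
    replicate_profiles: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.frac_planted <= 1.0:
            raise ValueError("frac_planted must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.base_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("base_freq_range must satisfy 0 <= lo <= hi <= 1")
        if self.frac_planted > 0 and not self.effects:
            raise ValueError("frac_planted > 0 requires at least one effect")

    @property
    def n_planted(self) -> int:
        return int(round(self.frac_planted * self.n_variants))


def _truth_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-variant ground truth shared by all cohorts of a run."""
    n = config.n_variants
    lo, hi = config.base_freq_range
    base = rng.uniform(lo, hi, size=n)
    planted = np.zeros(n, dtype=bool)
    planted_idx = rng.choice(n, size=config.n_planted, replace=False)
    planted[planted_idx] = True

    freqs = {g: base.copy() for g in GROUPS}
    pair = np.array([""] * n, dtype=object)
    profile = np.array([""] * n, dtype=object)
    for k, vi in enumerate(planted_idx):
        eff = config.effects[k % len(config.effects)]
        g_high, g_low = eff.pair
        mid = 0.5 * (eff.f_high + eff.f_low)
        for g in GROUPS:
            freqs[g][vi] = mid
        freqs[g_high][vi] = eff.f_high
        freqs[g_low][vi] = eff.f_low
        pair[vi] = f"{g_high}-{g_low}"
        profile[vi] = f"{g_high}+{g_low}-"

    return pd.DataFrame(
        {
            "variant_id": [f"rs{1_000_000 + i}" for i in range(n)],
            "planted": planted,
            "pair": pair,
            "profile": profile,
            **{f"f_{g}": freqs[g] for g in GROUPS},
        }
    )


def _genotypes_for_cohort(
    truth: pd.DataFrame,
    config: SimulationConfig,
    cohort_label: str,
    rng: np.random.Generator,
    flip_direction: np.ndarray | None = None,
    c_freq: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, CohortDesign, pd.DataFrame]:
    n = config.n_variants
    npg = config.n_per_group
    freqs = {g: truth[f"f_{g}"].to_numpy().copy() for g in GROUPS}
    profile = truth["profile"].to_numpy().copy()
    if c_freq is not None:
        freqs["C"] = c_freq
    if flip_direction is not None:
        for vi in np.flatnonzero(flip_direction):
            g_high, g_low = truth.loc[vi, "pair"].split("-")
            freqs[g_high][vi], freqs[g_low][vi] = freqs[g_low][vi], freqs[g_high][vi]
            profile[vi] = f"{g_high}-{g_low}+"

    samples: list[str] = []
    blocks: list[np.ndarray] = []
    assignments: dict[str, tuple[str, str]] = {}
    for g in GROUPS:
        ids = [f"{cohort_label}_{g}{i:03d}" for i in range(npg)]
        samples.extend(ids)
        for s in ids:
            assignments[s] = (cohort_label, g)
        blocks.append(rng.binomial(2, freqs[g][None, :], size=(npg, n)).astype(np.int8))
    genotypes = np.concatenate(blocks, axis=0)
    if config.missing_rate > 0:
        genotypes[rng.random(genotypes.shape) < config.missing_rate] = -1

    variants = [
        Variant(chrom="1", pos=1000 + 100 * i, id=vid, ref="A", alt="G", gene=f"GENE{i // 10}")
        for i, vid in enumerate(truth["variant_id"])
    ]
    matrix = GenotypeMatrix(variants=variants, samples=samples, genotypes=genotypes)
    cohort_truth = truth.copy()
    cohort_truth["profile"] = profile
    cohort_truth["f_C"] = freqs["C"]
    return matrix, CohortDesign(assignments), cohort_truth


def simulate_cohort(
    config: SimulationConfig, cohort_label: str = "A"
) -> tuple[GenotypeMatrix, CohortDesign, pd.DataFrame]:
    """Simulate one cohort; fully reproducible from ``config.seed``.

    Returns the genotype matrix, the design, and the truth table (one row
    per variant: planted flag, target pair, true per-group frequencies and
    true profile).
    """
    rng = np.random.default_rng(config.seed)
    truth = _truth_frame(config, rng)
    return _genotypes_for_cohort(truth, config, cohort_label, rng)


def simulate_replication_pair(
    config: SimulationConfig, labels: tuple[str, str] = ("NI", "VADU")
) -> tuple[
    tuple[GenotypeMatrix, CohortDesign],
    tuple[GenotypeMatrix, CohortDesign],
    pd.DataFrame,
]:
    """Simulate two cohorts sharing one truth table.

    With ``replicate_profiles`` true (the default), planted variants have the
    same direction in both cohorts; when false, each cohort's direction is an
    independent coin flip, which reduces expected exact-profile matches to
    the chance level.  The background-control frequency of planted variants
    is redrawn per cohort between f_low and f_high.

    The returned truth table carries the shared V/P/K truth plus per-cohort
    columns ``f_C_<label>`` and ``profile_<label>``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _truth_frame(config, rng)
    planted = truth["planted"].to_numpy()
    out = []
    merged = truth.copy()
    for label in labels:
        flip = None
        if not config.replicate_profiles:
            flip = planted & (rng.random(config.n_variants) < 0.5)
        c_freq = truth["f_C"].to_numpy().copy()
        if planted.any():
            lows = np.minimum(
                truth.loc[planted, [f"f_{g}" for g in ("V", "P", "K")]].min(axis=1),
                truth.loc[planted, "f_C"],
            )
            highs = truth.loc[planted, [f"f_{g}" for g in ("V", "P", "K")]].max(axis=1)
            c_freq[planted] = rng.uniform(lows, highs)
        matrix, design, cohort_truth = _genotypes_for_cohort(
            truth, config, label, rng, flip_direction=flip, c_freq=c_freq
        )
        merged[f"f_C_{label}"] = cohort_truth["f_C"]
        merged[f"profile_{label}"] = cohort_truth["profile"]
        out.append((matrix, design))
    return out[0], out[1], merged


def simulate_catalog(
    matrix: GenotypeMatrix,
    seed: int = 0,
    catalog_fraction: float = 0.05,
    n_traits: int = 40,
    second_trait_fraction: float = 0.1,
    nr_fraction: float = 0.1,
    extra_ids: int = 0,
) -> pd.DataFrame:
    """Synthetic risk-allele catalog over a subset of the matrix's variants.

    Each selected variant gets a trait drawn from a small synthetic
    vocabulary, a parent term, a risk allele that is randomly the variant's
    ref or alt, and a reported risk-allele frequency (``NR`` for a fraction
    of entries, as in real catalog exports).  ``extra_ids`` appends entries
    for ids absent from the matrix, so joins can be tested against
    non-overlapping catalog content.
    """
    rng = np.random.default_rng(seed)
    traits = [f"Trait_{i:03d}" for i in range(n_traits)]
    trait_parent = {t: PARENT_TERMS[i % len(PARENT_TERMS)] for i, t in enumerate(traits)}

    n_pick = int(round(catalog_fraction * matrix.n_variants))
    picked = rng.choice(matrix.n_variants, size=n_pick, replace=False)
    rows = []

    def _entry(vid, ref, alt):
        trait = traits[rng.integers(len(traits))]
        risk = ref if rng.random() < 0.5 else alt
        raf = "NR" if rng.random() < nr_fraction else round(float(rng.uniform(0.05, 0.95)), 2)
        rows.append(
            {
                "SNPS": vid,
                "DISEASE/TRAIT": trait,
                "PARENT_TERM": trait_parent[trait],
                "RISK_ALLELE": risk,
                "RAF": raf,
            }
        )

    for vi in sorted(picked):
        v = matrix.variants[vi]
        _entry(v.id, v.ref, v.alt)
        if rng.random() < second_trait_fraction:
            _entry(v.id, v.ref, v.alt)
    for k in range(extra_ids):
        _entry(f"rs9{900_000 + k}", "A", "G")
    return pd.DataFrame(rows, columns=["SNPS", "DISEASE/TRAIT", "PARENT_TERM", "RISK_ALLELE", "RAF"])
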