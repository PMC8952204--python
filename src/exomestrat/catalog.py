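"""GWAS-catalog mapping, enrichment testing, and risk-allele stratification.

Differentiating SNPs are joined to a catalog table (a GWAS-catalog-download
compatible subset: SNP id, disease/trait, ontology parent term, risk allele,
reported risk-allele frequency).  Three analyses are built on the join:

* **Random-set enrichment** — is the number of catalog hits among the
  differentiating SNPs larger than expected for a random SNP set of the
  same size drawn from the scanned pool?  The null is resampled directly
  (draws without replacement), and the observed count is compared to the
  null median by a one-cell goodness-of-fit chi-square with 1 df.  The full
  null count distribution is also returned so an empirical tail probability
  is available.
* **Per-group trait enrichment** — for each (group, trait), a 2x2 Fisher
  test of the group's trait hits against the composition of the whole
  catalog as background.
* **Risk stratification** — catalog-matched variants whose risk-allele
  frequency (RAF) both differs between constitution groups (Fisher p < .05
  for at least one group pair) and separates at least one group from the
  background control are tabulated with per-group RAFs; the higher-RAF
  group of each differentiating pair is marked ``##`` and the lower ``*``.

RAF orientation: when the catalog risk allele equals the variant's alternate
allele, RAF is the alternate-allele frequency; when it equals the reference
allele, RAF is its complement; anything else is unalignable and the row is
excluded with a log message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import fisher
from .io import GenotypeMatrix, Variant, alt_allele_frequency

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ["SNPS", "DISEASE/TRAIT", "PARENT_TERM", "RISK_ALLELE", "RAF"]


@dataclass(frozen=True)
class EnrichmentResult:
    observed_count: int
    null_median: float
    chi_square: float | None
    p: float | None
    n_iter: int
    draw_size: int
    null_counts: np.ndarray = field(repr=False, default=None)


def parse_risk_allele(value: str) -> str:
    """Risk-allele string, tolerating the catalog dialect ``rsID-A``."""
    value = str(value).strip()
    if "-" in value:
        return value.rsplit("-", 1)[1]
    return value


def load_catalog(path) -> pd.DataFrame:
    """Read a catalog TSV; extra columns are ignored, RAF 'NR' kept as NaN
    with the original string preserved in ``RAF_raw``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog is missing columns {missing}")
    df = df[CATALOG_COLUMNS].copy()
    df["RISK_ALLELE"] = df["RISK_ALLELE"].map(parse_risk_allele)
    df["RAF_raw"] = df["RAF"]
    df["RAF"] = pd.to_numeric(df["RAF"], errors="coerce")
    bad = df["RAF"].notna() & ((df["RAF"] < 0) | (df["RAF"] > 1))
    if bad.any():
        raise ValueError("catalog RAF values must lie in [0, 1]")
    return df


def _normalized(catalog: pd.DataFrame) -> pd.DataFrame:
    cat = catalog.copy()
    cat["RISK_ALLELE"] = cat["RISK_ALLELE"].map(parse_risk_allele)
    if "RAF_raw" not in cat.columns:
        cat["RAF_raw"] = cat["RAF"]
        cat["RAF"] = pd.to_numeric(cat["RAF"], errors="coerce")
    return cat


def map_to_catalog(snp_ids, catalog: pd.DataFrame) -> pd.DataFrame:
    """Inner join of variant ids with the catalog: one row per (variant, trait)."""
    cat = _normalized(catalog)
    ids = pd.DataFrame({"SNPS": sorted(set(snp_ids))})
    return ids.merge(cat, on="SNPS", how="inner")


def parent_term_counts(matches: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Roll matched traits up to parent terms (the bar-summary view)."""
    keys = ["PARENT_TERM"] if by is None else [by, "PARENT_TERM"]
    return matches.groupby(keys, dropna=False).size().reset_index(name="n_snps")


def random_set_enrichment(
    pool_ids,
    diff_ids,
    catalog: pd.DataFrame,
    n_iter: int = 1_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Resampling null for the catalog-hit count of the differentiating set.

    Draws ``n_iter`` random subsets of ``len(diff_ids)`` (without
    replacement) from the scanned pool, counts each subset's catalog
    matches, and compares the observed count against the null median with a
    one-cell chi-square ((obs - med)^2 / med, 1 df).  A null median of zero
    leaves the statistic undefined (None).
    """
    pool = np.array(sorted(set(pool_ids)))
    diff = set(diff_ids)
    if not diff <= set(pool):
        raise ValueError("differentiating ids must be drawn from the pool")
    draw_size = len(diff)
    if draw_size > len(pool):
        raise ValueError("draw size exceeds pool size")
    catalog_ids = set(_normalized(catalog)["SNPS"])
    observed = len(diff & catalog_ids)

    rng = np.random.default_rng(seed)
    in_catalog = np.isin(pool, sorted(catalog_ids))
    counts = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        pick = rng.choice(len(pool), size=draw_size, replace=False)
        counts[i] = int(in_catalog[pick].sum())
    med = float(np.median(counts))
    if med == 0:
        stat, p = None, None
    else:
        stat = (observed - med) ** 2 / med
        p = float(chi2.sf(stat, df=1))
    return EnrichmentResult(
        observed_count=observed,
        null_median=med,
        chi_square=stat,
        p=p,
        n_iter=n_iter,
        draw_size=draw_size,
        null_counts=counts,
    )


def trait_enrichment(group_matches: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, trait) Fisher enrichment against the whole catalog.

    ``group_matches`` has one row per (group, variant, trait) — e.g. catalog
    matches of each group's differentiating SNPs with a ``group`` column.
    The 2x2 table is [group hits to trait, group hits to other traits;
    catalog entries for trait, other catalog entries].
    """
    cat = _normalized(catalog)
    cat_counts = cat.groupby("DISEASE/TRAIT").size()
    cat_total = int(cat_counts.sum())
    parent = cat.drop_duplicates("DISEASE/TRAIT").set_index("DISEASE/TRAIT")["PARENT_TERM"]

    rows = []
    for group, sub in group_matches.groupby("group"):
        trait_hits = sub.groupby("DISEASE/TRAIT").size()
        total_hits = int(trait_hits.sum())
        for trait, a in trait_hits.items():
            if trait not in cat_counts.index:
                raise ValueError(f"trait {trait!r} absent from catalog")
            a = int(a)
            b = total_hits - a
            c = int(cat_counts[trait])
            d = cat_total - c
            rows.append(
                {
                    "group": group,
                    "DISEASE/TRAIT": trait,
                    "PARENT_TERM": parent.get(trait),
                    "hits": a,
                    "group_total": total_hits,
                    "catalog_trait": c,
                    "catalog_total": cat_total,
                    "p": fisher.fisher_two_sided(a, b, c, d),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "DISEASE/TRAIT", "PARENT_TERM", "hits", "group_total",
            "catalog_trait", "catalog_total", "p",
        ],
    )


def align_risk_allele(variant: Variant, risk_allele: str, alt_freqs: dict) -> dict:
    """Orient per-group alternate-allele frequencies to the risk allele.

    Raises ``ValueError`` when the risk allele matches neither ref nor alt.
    """
    risk = parse_risk_allele(risk_allele)
    if risk == variant.alt:
        return dict(alt_freqs)
    if risk == variant.ref:
        return {g: (1.0 - f) if not np.isnan(f) else f for g, f in alt_freqs.items()}
    raise ValueError(
        f"risk allele {risk!r} matches neither ref {variant.ref!r} nor alt "
        f"{variant.alt!r} at {variant.id}"
    )


RISK_COLUMNS = [
    "variant_id", "gene", "trait", "parent_term", "risk_allele",
    "raf_V", "raf_P", "raf_K", "raf_pooled", "raf_C", "raf_catalog",
    "sig_group_pairs", "sig_control_pairs", "high_group", "low_group",
    "exceeds_catalog",
]


def risk_stratify(
    matrix: GenotypeMatrix,
    design,
    diff_results: pd.DataFrame,
    background: pd.DataFrame,
    catalog: pd.DataFrame,
    cohort: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Build the risk-stratification table for catalog-matched variants.

    Keeps variants with at least one significant group-group contrast AND
    at least one significant group-control contrast.  ``high_group`` marks
    the groups on the higher-RAF side of any significant pair (``##`` in
    the conventional table rendering), ``low_group`` the lower side (``*``).
    ``exceeds_catalog`` flags rows where some group's RAF is above the
    catalog's reported RAF (None when the catalog RAF is not reported).
    """
    cat = _normalized(catalog)
    sig_pairs = diff_results[diff_results["p"] < alpha]
    sig_ctrl = background[background["p"] < alpha]
    keep_ids = set(sig_pairs["variant_id"]) & set(sig_ctrl["variant_id"])
    matches = map_to_catalog(keep_ids, cat)
    if matches.empty:
        return pd.DataFrame(columns=RISK_COLUMNS)

    vidx = {v.id: i for i, v in enumerate(matrix.variants)}
    group_samples = {g: design.samples(cohort=cohort, group=g) for g in ("V", "P", "K", "C")}
    pooled = group_samples["V"] + group_samples["P"] + group_samples["K"]

    rows = []
    for _, m in matches.iterrows():
        vid = m["SNPS"]
        vi = vidx[vid]
        variant = matrix.variants[vi]
        alt_freqs = {g: alt_allele_frequency(matrix, vi, s) for g, s in group_samples.items()}
        alt_freqs["pooled"] = alt_allele_frequency(matrix, vi, pooled)
        try:
            raf = align_risk_allele(variant, m["RISK_ALLELE"], alt_freqs)
        except ValueError as e:
            logger.warning("unalignable risk allele, row excluded: %s", e)
            continue

        v_pairs = sig_pairs[sig_pairs["variant_id"] == vid]
        high, low = set(), set()
        for _, r in v_pairs.iterrows():
            ga, gb = r["pair"].split("-")
            if raf[ga] > raf[gb]:
                high.add(ga), low.add(gb)
            elif raf[gb] > raf[ga]:
                high.add(gb), low.add(ga)
        low -= high  # a group higher in any significant pair is marked high
        ctrl = sorted(sig_ctrl.loc[sig_ctrl["variant_id"] == vid, "pair"].unique())
        cat_raf = m["RAF"]
        exceeds = (
            None
            if pd.isna(cat_raf)
            else bool(max(raf[g] for g in ("V", "P", "K")) > float(cat_raf))
        )
        rows.append(
            {
                "variant_id": vid,
                "gene": variant.gene,
                "trait": m["DISEASE/TRAIT"],
                "parent_term": m["PARENT_TERM"],
                "risk_allele": m["RISK_ALLELE"],
                "raf_V": raf["V"], "raf_P": raf["P"], "raf_K": raf["K"],
                "raf_pooled": raf["pooled"], "raf_C": raf["C"],
                "raf_catalog": cat_raf,
                "sig_group_pairs": ";".join(sorted(v_pairs["pair"].unique())),
                "sig_control_pairs": ";".join(ctrl),
                "high_group": ";".join(sorted(high)),
                "low_group": ";".join(sorted(low)),
                "exceeds_catalog": exceeds,
            }
        )
    return pd.DataFrame(rows, columns=RISK_COLUMNS)
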