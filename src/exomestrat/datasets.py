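"""Bundled reference data.

``load_reference_risk_table`` returns the risk-stratification table reported
by a two-cohort exome study of Ayurvedic constitution types (NI and Vadu
cohorts, 18 diploid individuals per group): for each disease/trait
associated SNP, the risk-allele frequency (RAF) in each constitution group
(V, P, K), the pooled V+P+K frequency, the background-control frequency,
the GWAS-catalog RAF where reported, and the contrasts found significant.

With 18 diploids per group the underlying allele counts are recoverable as
``round(RAF x 36)``, so the table doubles as a validation input: the
significant group-pair calls can be re-derived from reconstructed counts
with the package's own Fisher test.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import fisher

GROUP_COLUMNS = {"V": "raf_V", "P": "raf_P", "K": "raf_K", "C": "raf_C"}


def load_reference_risk_table() -> pd.DataFrame:
    """The bundled reference risk table (one row per SNP/trait/cohort)."""
    with resources.files("exomestrat.data").joinpath("reference_risk_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"snp": str})
    for col in ("raf_V", "raf_P", "raf_K", "raf_pooled", "raf_C"):
        df[col] = pd.to_numeric(df[col])
    df["raf_catalog"] = pd.to_numeric(df["raf_catalog"], errors="coerce")
    return df


def reconstruct_counts(raf: float, n_diploid: int = 18) -> tuple[int, int]:
    """(risk, other) allele counts from a frequency over ``2 x n_diploid`` alleles."""
    total = 2 * n_diploid
    k = int(round(raf * total))
    return k, total - k


def reference_pair_pvalues(n_diploid: int = 18) -> pd.DataFrame:
    """Two-sided Fisher p for every listed contrast, from reconstructed counts.

    Group-group contrasts use the two groups' RAFs; group-control contrasts
    use the group and background-control RAFs.  Returns one row per
    (cohort, snp, trait, contrast).
    """
    table = load_reference_risk_table()
    rows = []
    for _, r in table.iterrows():
        for contrast in r["contrasts"].split(";"):
            ga, gb = contrast.split("-")
            a, b = reconstruct_counts(r[GROUP_COLUMNS[ga]], n_diploid)
            c, d = reconstruct_counts(r[GROUP_COLUMNS[gb]], n_diploid)
            rows.append(
                {
                    "cohort": r["cohort"],
                    "snp": r["snp"],
                    "gene": r["gene"],
                    "trait": r["trait"],
                    "contrast": contrast,
                    "a": a, "b": b, "c": c, "d": d,
                    "p": fisher.fisher_two_sided(a, b, c, d),
                }
            )
    return pd.DataFrame(rows)
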