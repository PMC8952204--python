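"""Genotype and cohort-design ingestion.

Reads a multi-sample diploid VCF together with a sample sheet assigning each
sample to a cohort and one of the four study groups — the three extreme
constitution types *Vata* (V), *Pitta* (P), *Kapha* (K) and the unstratified
background control (C) — into an alternate-allele dosage matrix.

Conventions
-----------
* Genotypes are stored as alt-allele dosage in {0, 1, 2}; ``-1`` marks a
  missing call.  Phase is discarded: every downstream test is allelic.
* Any genotype containing a missing allele (``./.`` or half-calls such as
  ``0/.``) is treated as fully missing.
* Multi-allelic sites are split into one biallelic record per alternate
  allele; at each split record, other alternate alleles count toward
  neither cell of the 2x2 table (they are treated as reference for that
  record) — the simplest convention consistent with allelic counting.
* Variants without an rsID are identified by ``chrom:pos``.
* Sex chromosomes are treated as diploid autosomes.
* Coordinates are 1-based as in VCF; inputs are assumed build-harmonized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("V", "P", "K", "C")


@dataclass(frozen=True)
class Variant:
    """A biallelic variant record."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    gene: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.id:
            raise ValueError("variant id must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity across cohorts when rsIDs are absent."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-dosage matrix.

    ``genotypes`` has shape ``(n_samples, n_variants)``, dtype int8, entries
    in {0, 1, 2} or -1 for missing.
    """

    variants: list[Variant]
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"({len(self.samples)} samples, {len(self.variants)} variants)"
            )
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype entries must be in {0,1,2} or -1 (missing)")
        self._sample_pos = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def sample_index(self, sample_ids) -> np.ndarray:
        try:
            return np.array([self._sample_pos[s] for s in sample_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def variant_index_by_id(self, variant_ids) -> np.ndarray:
        pos: dict[str, int] = {}
        for i, v in enumerate(self.variants):
            pos.setdefault(v.id, i)
        missing = [vid for vid in variant_ids if vid not in pos]
        if missing:
            raise KeyError(f"variants not in matrix: {missing[:5]}")
        return np.array([pos[vid] for vid in variant_ids], dtype=np.intp)


@dataclass
class CohortDesign:
    """Sample -> (cohort, group) assignment."""

    assignments: dict[str, tuple[str, str]]

    def __post_init__(self):
        for s, (_, g) in self.assignments.items():
            if g not in GROUPS:
                raise ValueError(f"sample {s!r} has group {g!r}; must be one of {GROUPS}")

    @property
    def cohorts(self) -> set[str]:
        return {c for c, _ in self.assignments.values()}

    def samples(self, cohort: str | None = None, group: str | None = None) -> list[str]:
        """Samples matching the given cohort and/or group, in insertion order."""
        return [
            s
            for s, (c, g) in self.assignments.items()
            if (cohort is None or c == cohort) and (group is None or g == group)
        ]

    def group_sizes(self, cohort: str | None = None) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, (c, g) in self.assignments.items():
            if cohort is None or c == cohort:
                out[g] = out.get(g, 0) + 1
        return out


def read_sample_sheet(sheet_path) -> CohortDesign:
    """Read a TSV with header ``sample<TAB>cohort<TAB>group``."""
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    required = {"sample", "cohort", "group"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return CohortDesign(
        {r["sample"]: (r["cohort"], r["group"]) for _, r in sheet.iterrows()}
    )


def read_genotypes(vcf_path, sheet_path) -> tuple[GenotypeMatrix, CohortDesign]:
    """Read a diploid VCF plus sample sheet into (GenotypeMatrix, CohortDesign).

    Samples listed in the sheet must all be present in the VCF (error
    otherwise); VCF samples absent from the sheet are dropped with a warning.
    Multi-allelic sites are split into biallelic records (see module notes).
    """
    from cyvcf2 import VCF

    vcf_path, sheet_path = Path(vcf_path), Path(sheet_path)
    for p in (vcf_path, sheet_path):
        if not p.exists():
            raise FileNotFoundError(p)
    design = read_sample_sheet(sheet_path)

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    sheet_samples = set(design.assignments)
    absent = sorted(sheet_samples - set(vcf_samples))
    if absent:
        raise ValueError(f"samples in sheet but not in VCF: {absent[:5]}")
    extra = [s for s in vcf_samples if s not in sheet_samples]
    if extra:
        logger.warning("dropping %d VCF sample(s) absent from sheet: %s", len(extra), extra[:5])
    keep_cols = np.array([i for i, s in enumerate(vcf_samples) if s in sheet_samples])
    samples = [vcf_samples[i] for i in keep_cols]

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int16)[keep_cols]
        any_missing = (alleles < 0).any(axis=1)
        gene = rec.INFO.get("GENE")
        for alt_i, alt in enumerate(rec.ALT, start=1):
            vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
            variants.append(
                Variant(chrom=rec.CHROM, pos=rec.POS, id=vid, ref=rec.REF, alt=alt, gene=gene)
            )
            dos = (alleles == alt_i).sum(axis=1).astype(np.int8)
            dos[any_missing] = -1
            columns.append(dos)
    genotypes = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(variants=variants, samples=samples, genotypes=genotypes)
    return matrix, design


def call_rate(matrix: GenotypeMatrix, variant_index: int, sample_subset) -> float:
    """Fraction of the subset with a non-missing genotype at the variant."""
    idx = matrix.sample_index(sample_subset)
    if idx.size == 0:
        raise ValueError("sample subset must be non-empty")
    col = matrix.genotypes[idx, variant_index]
    return float((col >= 0).sum()) / idx.size


def filter_by_call_rate(
    matrix: GenotypeMatrix, pair_samples, threshold: float = 0.5
) -> np.ndarray:
    """Indices of variants with call rate >= threshold over the pair's samples.

    The boundary follows the removal rule "call rate below the threshold":
    a variant at exactly the threshold is kept.  Filtering is intended to be
    recomputed independently for every pairwise comparison.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    idx = matrix.sample_index(pair_samples)
    if idx.size == 0:
        raise ValueError("sample subset must be non-empty")
    rates = (matrix.genotypes[idx] >= 0).mean(axis=0)
    return np.flatnonzero(rates >= threshold)


def alt_allele_frequency(matrix: GenotypeMatrix, variant_index: int, group_samples) -> float:
    """Alternate-allele frequency: dosage sum / (2 x non-missing count).

    Returns NaN when every genotype in the group is missing.
    """
    idx = matrix.sample_index(group_samples)
    col = matrix.genotypes[idx, variant_index]
    nm = col >= 0
    n = int(nm.sum())
    if n == 0:
        return float("nan")
    return float(col[nm].sum()) / (2 * n)


def write_vcf(matrix: GenotypeMatrix, path, design: CohortDesign | None = None) -> None:
    """Write the matrix as a plain-text VCF 4.2 file (dosage -> unphased GT)."""
    path = Path(path)
    gt_strings = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    contigs = []
    for v in matrix.variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exomestrat\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            info = f"GENE={v.gene}" if v.gene else "."
            vid = "." if v.id == f"{v.chrom}:{v.pos}" else v.id
            gts = "\t".join(gt_strings[int(g)] for g in matrix.genotypes[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{gts}\n")


def write_sample_sheet(design: CohortDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcohort\tgroup\n")
        for s, (c, g) in design.assignments.items():
            fh.write(f"{s}\t{c}\t{g}\n")


def write_dosage_tsv(matrix: GenotypeMatrix, path) -> None:
    """Serialize dosages as a TSV: one row per variant, one column per sample."""
    df = pd.DataFrame(
        matrix.genotypes.T,
        index=pd.Index(matrix.variant_ids, name="variant_id"),
        columns=matrix.samples,
    )
    df = df.astype(object).where(df >= 0, ".")
    df.to_csv(path, sep="\t")
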