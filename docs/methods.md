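# Methods

## Statistical model

All association testing is **allelic**: each non-missing diploid genotype
contributes two alleles, and a comparison of groups A and B at one variant
is the 2×2 table

|         | alt | ref |
|---------|-----|-----|
| group A | a   | b   |
| group B | c   | d   |

with `a + b = 2 ×` (non-missing samples in A).  The two-sided p-value is
the minimum-likelihood Fisher rule: with margins fixed, `a` is
hypergeometric, and p sums the probabilities of all tables whose
probability does not exceed the observed one (no mid-p, no doubling of the
one-sided tail).  This is the convention of PLINK's allelic `--fisher`
test and of R's `fisher.test`; probabilities are compared with a relative
slack of 1e-7 to absorb floating-point noise around exact ties, and the
implementation is verified against exact rational enumeration on every
table with grand total ≤ 40.

The allelic model implicitly assumes alleles within a genotype are
independent draws (Hardy–Weinberg equilibrium within groups); no covariate
adjustment, genotypic model or HWE test is offered.

### Permutation filtering

For each pairwise comparison the group labels of that comparison's samples
(e.g. the 36 samples of V∪K) are reshuffled uniformly with group sizes
preserved, and the scan is recomputed on the identical call-rate-filtered
variant set — the missingness pattern is label-independent, so the filter
is not recomputed per permutation.  The per-SNP empirical p-value is the
add-one-corrected exceedance fraction `(r + 1)/(n_perm + 1)`, which cannot
be zero.  Retention requires both the nominal p ≤ α and the empirical
p ≤ α; the permutation-only rule is available
(`PermutationConfig(require_nominal=False)`).  Because shuffling never
changes a variant's pooled allele counts, all permuted tables of one
variant share column margins, and p-values are served from cached
per-margin lookup tables — this makes 80,000-iteration runs practical;
the package default is 2,000 (the empirical-p formula is scale-free, only
its resolution changes).

### Replication and contrasts

Cohorts are analyzed fully independently and compared at three nested
levels: shared genes; identical variants (identity by rsID, else by
(chrom, pos, ref, alt); mismatched ref/alt orientation is an error, never
silently flipped); and identical variants retained for the same group pair
with the identical direction profile.  Exact frequency ties get a tie
marker and can never match at level 3 — replication claims require a
strict direction.  By default level-2 identity accepts retention in any
pair (`same_pair=True` tightens it).  Group-vs-control Fisher contrasts
are computed for a supplied SNP list — conventionally the level-3 set —
with a flag to run them on a cohort's whole retained set.

### Catalog analyses

The random-set enrichment null redraws `|diff_set|` SNPs from the scanned
pool without replacement `n_iter` times and counts catalog matches; the
observed count is compared to the null median by a one-cell goodness-of-fit
chi-square `(obs − med)² / med` with 1 df.  The chi-square layout is one
defensible reading of a test named only by family; the full null count
distribution is therefore also returned so an empirical tail probability
can be used instead.  A null median of zero leaves the statistic undefined
(reported as such).  Per-(group, trait) enrichment uses a 2×2 Fisher test
of the group's trait hits against the composition of the entire catalog —
again an interpretation, recorded here deliberately.  Risk-allele
orientation: RAF equals the alternate-allele frequency when the catalog
risk allele is the alternate allele, its complement when it is the
reference allele; anything else is unalignable and excluded with a log
message.  The risk table keeps variants with at least one significant
group-group AND one significant group-control contrast, marking the
higher-RAF side of each significant pair (`##` / `*` convention); a group
that is the higher side in any significant pair is never down-marked by
another pair.

### Power

Power of the allelic test is estimated by drawing each group's allele
count as `Binomial(2n, p)` — identical in distribution to per-sample HWE
genotype sampling — and counting rejections.  Raw per-size estimates are
reported without monotone smoothing.  For `2n ≤ 20` the suite checks the
simulation against exact power obtained by enumerating the joint binomial
grid.

## Synthetic data

The generator emulates the target study design: per cohort, four groups
(V, P, K, C) of `n_per_group = 18`, `n_variants` independent biallelic
variants, genotypes `Binomial(2, f_group)`, missingness i.i.d. per
genotype at rate 0.02 (typical post-QC exome genotype missingness).  Null
variants share one frequency across all groups, drawn uniform on
(0.05, 0.95) — a flat, common-variant spectrum chosen for test
transparency rather than realism.  Planted variants place `(f_high,
f_low)` on a target pair (default 0.8 vs 0.2 on V–K) and the midpoint on
the remaining groups so the pooled frequency stays stable.  In a
replication pair, planted directions are shared across cohorts
(independent coin flips when `replicate_profiles=False`) while the
control-group frequency of planted variants is redrawn per cohort —
controls are an unstratified mixture of types, so their frequency need not
replicate even where group profiles do.

What the generator does **not** model: linkage disequilibrium, realistic
site-frequency spectra, relatedness, population substructure, batch or
platform effects, genotype-calling error.  Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under its own assumptions, not robustness of the design to real exome
artifacts.

## Numerical and design choices

* Genotypes are alt-allele dosage {0, 1, 2}, −1 missing; phase is
  discarded.  Any genotype containing a missing allele (`./.`, `0/.`) is
  fully missing.
* Multi-allelic sites split into one biallelic record per alternate
  allele; other alternates count as reference for that record.
* Call-rate boundary: "below 50% removed" is strict, so exactly 0.5 is
  kept; the filter is recomputed per pairwise comparison.
* Variants lacking an rsID are identified as `chrom:pos`.  Sex chromosomes
  are treated as diploid autosomes.  Coordinates are 1-based; inputs are
  assumed build-harmonized (no liftover).
* Permutation exceedance uses `p_perm ≤ p_obs × (1 + 1e-9)`: identical
  tables produce bit-identical p-values through the shared code path, so
  the slack is purely defensive.
* RNG: a single master seed; per-stage streams are spawned via
  `numpy.random.SeedSequence`, recorded in the run manifest.  Reruns are
  byte-identical.
* No multiple-testing correction in the scan stage — nominal 0.05 followed
  by permutation filtering is the procedure itself.

## Problem sizes

Defaults were chosen so a laptop-scale run completes in seconds to
minutes: 2,000 permutations, 1,000–10,000 power simulations per point,
1,000 enrichment draws, and simulation studies of 2,000–5,000 variants.
The calibration and recovery checks in the test suite and acceptance
script use 5,000-variant null simulations and 2,000-variant two-cohort
planted simulations (50 planted V–K variants at 0.8 vs 0.2).
Publication-scale settings (80,000 permutations, 10⁵ variants) are plain
configuration changes; the permutation engine's margin caching keeps them
tractable.

## Known limitations

* The enrichment chi-square compares an observed count to a resampled
  median; its null distribution is only approximately χ²(1) — prefer the
  returned empirical null for small draws.
* Fisher's exact test is conservative at these allele counts; permutation
  retention inherits that conservatism (observed null retention ≈ 2% at
  α = 5%).
* The bundled reference risk table stores frequencies rounded to two
  decimals; reconstructed allele counts are exact only because group sizes
  are 18 diploids.
* Group-trait enrichment treats each (variant, trait) match row as a unit;
  SNPs associated with many traits weigh accordingly.
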