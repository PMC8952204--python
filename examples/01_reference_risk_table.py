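"""Re-derive the reference risk table's significance calls from frequencies.

The bundled table reports risk-allele frequencies per constitution group
(18 diploids each), so allele counts are recoverable as round(RAF x 36).
For each listed contrast we rebuild the 2x2 allele table and apply the
two-sided Fisher exact test: every group-group call should come out
significant at 0.05.
"""

from exomestrat import reference_pair_pvalues

pvals = reference_pair_pvalues(n_diploid=18)
group_group = pvals[~pvals["contrast"].str.endswith("C")]
print(group_group[["cohort", "snp", "gene", "contrast", "a", "c", "p"]].to_string(index=False))
n_sig = (group_group["p"] <= 0.05).sum()
print(f"\n{n_sig}/{len(group_group)} group-group contrasts significant at p <= 0.05")
print("('a' and 'c' are risk-allele counts out of 36 alleles in each group)")
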