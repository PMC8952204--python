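# Full-pipeline configuration (desk scale).  Either give a `simulate` block
# (two cohorts are generated) or an `inputs` block with per-cohort VCF +
# sample-sheet paths and optionally `catalog_path`.
outdir: exomestrat_run
seed: 42
alpha: 0.05
call_rate_threshold: 0.5
n_perm: 2000          # 80000 for a publication-scale run
simulate:
  n_per_group: 18
  n_variants: 2000
  frac_planted: 0.02
  missing_rate: 0.02
power_sizes: [18, 50, 100, 500, 1000, 10000]
power_n_sim: 1000
power_freqs: [[0.8, 0.2]]
enrichment_n_iter: 1000
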