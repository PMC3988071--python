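# Full-pipeline run mirroring the study design: a ~1000-subject cohort with
# 54 additive BMD-decreasing SNPs, a rare +3 SD protective variant, extreme
# ascertainment at sum Z >= 4, five-bin risk scores, medcouple skewness,
# pedigree cosegregation and an 88-gene expression screen.
seed: 1
out_dir: hbm_run
n_boot: 1000
hbm_threshold: 4.0
fold_threshold: 2.0
outlier_fold: 5.0
sim:
  n_subjects: 1001
  n_snps: 54
  maf_range: [0.05, 0.5]
  noise_sd: 0.9
  site_correlation: 0.6
  missing_rate: 0.02
  rare_variant:
    carrier_frequency: 0.02
    protective_effect: 3.0
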