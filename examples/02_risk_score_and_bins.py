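"""Weighted genetic risk score on a synthetic cohort.

Simulates a ~1000-subject cohort genotyped at 54 BMD-decreasing SNPs, scores
every subject (0x/1x/2x the per-allele effect, missing calls mean-imputed
from the cohort), normalizes by the mean effect size, sorts scores into five
width-4 bins and reports the bin-level score/phenotype correlation.
"""

import warnings

from hbmkit import SimulationConfig, bin_correlation, bin_summary, score_cohort, simulate_cohort

bundle = simulate_cohort(SimulationConfig(seed=1))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # terminal-bin clamping is expected here
    scored = score_cohort(bundle.genotypes, bundle.effects)

summary = bin_summary(scored.assignment, bundle.subjects["ls_z"])
corr = bin_correlation(summary)

print("bin      count  mean LS Z   SE")
for _, row in summary.iterrows():
    print(f"{row['bin_label']:>7} {row['count']:>6} "
          f"{row['mean_phenotype']:>9.3f} {row['se_phenotype']:>6.3f}")
print(f"\nPearson r (bin midpoint vs mean LS Z) = {corr.r:.3f}, "
      f"p = {corr.p_value:.4f}, r^2 = {corr.r_squared:.2f}")
# A strongly negative r reproduces the additive-architecture signature: the
# more risk alleles a subject carries, the lower the bone-density phenotype.
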