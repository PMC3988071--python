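# hbmkit

Extreme-phenotype bone-density genetics toolkit: a tested, reusable
implementation of a high-bone-mass (HBM) cohort analysis for postmenopausal
DXA-scanned populations.

Bone mineral density (BMD) is approximately Gaussian in the population, and
its extreme upper tail — high bone mass, ascertained here as a **sum
Z-score** (lumbar-spine Z + hip Z) of at least 4 — can arise two ways: many
common risk alleles of small additive effect (few of them in an HBM case),
or a single rare, highly penetrant protective variant. `hbmkit` provides
the statistical machinery to investigate both hypotheses in a cohort:

- **Cohort module** — subject tables, extreme-phenotype ascertainment
  (`sum Z >= 4`), availability filters and prevalence, with a packaged
  16-case study table.
- **Genetic risk score (GRS)** — the effect-size-weighted score
  `S_i = Σ_j g_ij β_j` (dosage `g ∈ {0,1,2}` of the BMD-decreasing allele,
  per-allele effect `β_j > 0`), mean-imputation of missing genotypes from a
  reference cohort, normalization `S_i / mean(β)` onto an effective
  risk-allele-count scale, width-4 score bins and the bin-level Pearson
  correlation between score and phenotype.
- **Robust skewness** — the medcouple `MC = med h(x_i, x_j)` over pairs
  straddling the sample median, with
  `h = ((x_j − m) − (m − x_i)) / (x_j − x_i)`, tail-weight measures
  LMC/RMC, seeded percentile-bootstrap confidence intervals, and the
  CI-overlap rule for comparing a cohort with a small extreme subgroup.
- **Cosegregation** — dominant, fully penetrant cosegregation checks of a
  candidate variant in nuclear pedigrees, with packaged family fixtures.
- **Expression screen** — qPCR relative quantification (`2^−ΔCt`),
  reference-gene selection by minimum cross-sample CV, a two-fold
  case/control screen, expression-vs-Z trend fits (slope, R²; no p-values at
  these sample sizes) and fold-outlier flags.
- **Synthetic cohorts** — a seeded generator producing genotypes in
  Hardy-Weinberg equilibrium, additive phenotypes with correlated
  lumbar-spine/hip Z-scores, rare protective variants, Mendelian nuclear
  pedigrees and triplicate Ct panels, so the entire analysis is exercisable
  and testable without any external data.

## Worked example

```python
import warnings
from hbmkit import (SimulationConfig, simulate_cohort, score_cohort,
                    bin_summary, bin_correlation)

bundle = simulate_cohort(SimulationConfig(seed=1))     # 1001 subjects, 54 SNPs
with warnings.catch_warnings():
    warnings.simplefilter("ignore")                    # terminal-bin clamping
    scored = score_cohort(bundle.genotypes, bundle.effects)
summary = bin_summary(scored.assignment, bundle.subjects["ls_z"])
corr = bin_correlation(summary)
print(summary[["bin_label", "count", "mean_phenotype"]])
print(f"r = {corr.r:.3f}, p = {corr.p_value:.4f}, r^2 = {corr.r_squared:.2f}")
```

prints

```
  bin_label  count  mean_phenotype
      24-28    107           0.467
      28-32    215           0.240
      32-36    327          -0.070
      36-40    233          -0.174
      40-44    119          -0.323
r = -0.983, p = 0.0026, r^2 = 0.97
```

Reading: the five score bins partition the cohort with the familiar
bell-shaped counts (hundreds centrally, ~a hundred in each clamped terminal
bin), and the mean lumbar-spine Z-score falls monotonically as the risk
score rises — the signature of an additive polygenic architecture. The
strongly negative bin-level Pearson correlation summarizes that gradient.

Each capability has a narrative script under `examples/` (ascertainment,
scoring, skewness, cosegregation, expression screen, full pipeline). The
full pipeline is also available from the shell:

```bash
hbm run --config examples/paper_like.yaml --out-dir hbm_run
hbm ascertain --subjects study-cases --n-scanned 1600
hbm segregate --pedigree carrier-trio
```

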