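# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `hbmkit`, and what the synthetic-data tests do and do not
establish about real cohorts.

## Phenotype and ascertainment model

The quantitative phenotype is bone mineral density on a standardized scale.
Subjects carry two DXA Z-scores — lumbar spine (`ls_z`) and hip/femoral neck
(`hip_z`, the two site names are used interchangeably) — and the
ascertainment statistic is their sum. A subject is a high-bone-mass (HBM)
case when `sum_z >= threshold`, threshold 4 by default and inclusive ("equal
to or greater than"); the threshold is shared by the cohort, pedigree and
pipeline modules. Printed subject tables round to one decimal, so the
`sum = ls + hip` consistency check warns only beyond an absolute tolerance
of 0.05. Prevalence is `100 · n_cases / n_scanned`; the reporting helper
rounds half-up to two decimals (10/1600 → "0.63%"), since banker's rounding
would print 0.62 for the exact value 0.625.

## Genetic risk score

Per SNP, the score is `dosage × β` with `β > 0` the per-allele phenotype
decrease (risk-allele orientation: homozygous risk = 2β, heterozygous = β,
homozygous alternative = 0). Missing genotypes are replaced by the mean of
that SNP's scores over the non-missing subjects of a designated reference
cohort; mean imputation preserves the cohort mean while attenuating group
variance, which is acceptable for the rank/bin analyses performed here. The
raw score is the per-subject sum; the normalized score divides by the mean
β over the SNP panel in use, yielding an effective-risk-allele count in
`[0, 2·n_snps]`. "Mean effect size" is read as the mean of per-SNP betas
(not a per-subject average): it is the only reading that produces the
allele-count bin scale. SNP exclusions (e.g. an assay with conflicting
calls) are applied before scoring and the panel mean β is recomputed on the
retained SNPs. Whether a scored subgroup's own genotypes should enter the
reference means is a design choice; the default reference is the cohort
supplied by the caller, and subgroups can be scored against cohort-derived
edges and means explicitly.

Bins are equal-width (4 normalized-score units) with edges at multiples of
4; the default 5-bin window is centered on the bin containing the cohort
median, and scores outside the window are clamped into the terminal bins
with a warning — reproducing the familiar histogram shape in which terminal
bins collect the tails. Intervals are left-closed/right-open with the last
bin closed so the maximum score is never lost. Bin summaries report count,
mean phenotype and `se = sd/√n` (NaN for singleton bins). The bin-level
correlation is Pearson's r between bin midpoints and bin mean phenotypes
(midpoint and bin index are equivalent for equal-width bins), with the
conventional two-sided t test on `n_bins − 2` degrees of freedom; it
requires at least three non-empty bins and returns NaN-marked results for
zero-variance inputs.

## Medcouple skewness

For a sample with median m, the medcouple is the median of the kernel
`h(x_i, x_j) = ((x_j − m) − (m − x_i)) / (x_j − x_i)` over pairs with
`x_i <= m <= x_j`. Observations tied with the median use the sign kernel
`h = sign(i + j − 1 − k)` with the k tied observations indexed from either
side; this keeps the statistic well defined for heavily tied small samples.
The implementation is the exact O(n²) kernel evaluation, vectorized; a
pure-Python exhaustive enumeration serves as the test oracle and the two
agree bit-for-bit (the vectorized numerator `z_j + z_i` with `z = x − m`
equals the textbook form exactly in IEEE-754 arithmetic; the denominator is
computed as `x_j − x_i` in both routes). The even-n median is the mean of
the two central order statistics. Degenerate inputs (n < 3 or zero spread)
yield NaN-marked statistics rather than exceptions so batch pipelines
survive degenerate bins.

Tail weights: `LMC = −MC(x ≤ m)` and `RMC = MC(x ≥ m)`; both are ≈ 0.2 for
Gaussian tails and grow with tail heaviness.

Confidence intervals use a seeded percentile bootstrap (default 2000
resamples, level 95%). The interval-construction method is deliberately
pluggable in spirit: the percentile bootstrap was chosen because it is
distribution-free and directly testable by coverage simulation (measured
coverage ≈ 96% for symmetric n = 1000 samples). Two distributions are
compared by the overlap rule: overlapping intervals mean no skewness
difference can be claimed — with an extreme subgroup of ~11 subjects the
interval spans more than a unit of the [−1, 1] scale, so the expected
outcome of a cohort-vs-extreme comparison is "overlapping".

## Pedigree cosegregation

The dominant-model check declares a pedigree `consistent` when every member
with known carrier status and known phenotype is concordant
(carrier ⇔ affected), `inconsistent` on any discordance, and
`uninformative` with fewer than two informative members. Full penetrance is
assumed because the inference the check supports is drawn from very small
nuclear families; discordance counts are reported so partial-penetrance
judgments remain possible downstream. Members with unknown carrier status
or missing phenotype are listed as uninformative, never as evidence. The
verdict is invariant under member reordering.

## qPCR screen

Quantification is ΔCt with a fixed amplification efficiency of 2 (perfect
doubling): `expression = 2^−(meanCt_gene − meanCt_ref)` per sample using
replicate-mean Ct. No calibrator sample is used (ΔΔCt would cancel in the
group-mean ratios the screen takes). The reference gene is the candidate
whose per-sample mean Ct has minimal coefficient of variation across
samples — reference stability is conventionally judged on the Ct scale —
with lexicographic tie-breaking under a warning. The screen keeps genes
whose case/control mean-expression ratio is ≥ fold or ≤ 1/fold (default 2);
the rule is symmetric in direction, and genes with undefined ratios are
reported unscreenable rather than dropped. Trend fits are ordinary least
squares of expression on sum Z, reported as slope/intercept/R² without
p-values: with a handful of primary-culture donors the regression
assumptions cannot be verified, so the fit is descriptive. Single-case
outliers are flagged at ≥ fold (default 5) above or below the control mean.
A replicate-outlier drop rule (discard a replicate more than one cycle from
the triplicate median) exists but is off by default.

## Synthetic-data generator

The generator emulates the study design, not any particular dataset.

**Genotypes.** `n_snps` independent biallelic SNPs; risk-allele frequency
drawn uniformly from `maf_range`, dosages Binomial(2, p) (Hardy-Weinberg
equilibrium). No linkage disequilibrium, by design. Missingness is injected
uniformly at random (MCAR) and marked NaN, distinct from dosage 0;
phenotypes are always generated from the complete matrix
(`simulate_cohort` sequences generate → phenotype → mask).

**Phenotype.** `P_i = baseline − Σ_j β_j g_ij + N(0, noise_sd)`, then
standardized against the simulated cohort. Lumbar-spine and hip Z-scores
are `√ρ · L_i + √(1−ρ) · ε` with independent ε per site, each
re-standardized, so the two sites correlate at ρ (`site_correlation`,
default 0.6 — a plausible within-subject DXA correlation; no empirical
value is available, so sensitivity to it should be checked before drawing
conclusions that depend on the tail mass). Under the defaults the sum-Z
tail `P(sum_z ≥ 4) ≈ 1.3%`, the right order of magnitude for HBM
prevalence figures (0.2–1%).

**Defaults.** 1001 subjects (a realistic genotyped-cohort size), 54
effective SNPs (a 55-SNP panel minus one excluded assay),
β ~ U(0.04, 0.12) phenotype-SD per allele, MAF ~ U(0.05, 0.5), noise_sd
0.9, missingness 2%. These give the SNP panel a heritability
`Σ 2p(1−p)β² / Var(P)` of ≈ 14% — deliberately at the generous end of
common-variant architectures so that the five-bin phenotype gradient the
analysis targets emerges cleanly at n ≈ 1000, the regime the package
illustrates. The heritability bookkeeping identity is verified by test.

**Rare protective variant.** An optional fully penetrant dominant variant:
carriers (Bernoulli with `carrier_frequency`, default 0.02, i.e. allele
frequency 1%) receive a fixed `protective_effect` (default +3 SD) on the
standardized latent phenotype; a heterozygote expresses the full shift. On
the sum-Z scale the expected carrier shift is `2√ρ · 3 ≈ 4.6`, so most
carriers are HBM cases — reproducing the discordance scenario in which an
extreme-phenotype subject nevertheless carries a top-bin risk score.

**Pedigrees.** Nuclear families: proband, spouse, offspring. Offspring of a
carrier proband inherit the variant with probability 1/2 and carriers
express the shift; phenotypes are measured on the population reference
scale. Because family studies begin from an ascertained proband,
`founder_sum_z` lets the caller record the proband's observed phenotype
instead of drawing an unconditioned one. No polygenic transmission within
families is modeled — carrier/non-carrier contrasts only.

**Ct panels.** Per gene, a base Ct ~ U(22, 30); the designated reference
gene (default label B2M, base 21) has a constant true level across samples.
Trend genes' mean Ct varies linearly with sum Z (negative expression trend
⇔ positive Ct slope). Other genes receive per-sample biological offsets
normalized to exactly `biological_sd` (default 0.4 cycles), guaranteeing
every non-reference gene a variation floor. Replicate noise (default SD
0.15 cycles) is Gaussian but centered within each triplicate, so replicate
averaging recovers the designed per-sample mean exactly; this makes the
reference gene's minimal CV a construction-level guarantee rather than a
high-probability event, at the cost of replicates being exchangeable rather
than fully independent. Downstream statistics use replicate means, so the
distinction does not affect them.

**Determinism.** All randomness flows through numpy `SeedSequence`s derived
from the config seed with fixed per-stage keys, so identical config + seed
gives bit-identical cohorts, pedigrees and panels regardless of call order,
and the full pipeline report is byte-reproducible.

## What the synthetic tests do and do not show

Passing tests establish that the estimators recover the structures the
generator plants — additive bin gradients, planted fold-changes, Mendelian
transmission, calibrated bootstrap coverage — under idealized conditions:
no LD, no population structure, no age/menopause covariates, MCAR
missingness, no genotyping error, no plate/batch effects, Gaussian noise
throughout. They do not validate effect-size estimates on real cohorts, and
the study's own per-subject data are not reproduced anywhere: printed
statistics from the original analysis serve only as qualitative shape
references (e.g. a bin correlation near −0.97 at n ≈ 1000, a
wide-interval/overlap conclusion at n = 11).

## Problem sizes used by the test suite

The packaged checks run at the sizes the analysis targets: 50 seeded
cohorts of n = 1001 × 54 SNPs for the bin-gradient property; 500 bootstrap
coverage replicates at n = 1000 with 100 resamples per interval (the
default of 2000 resamples is for data analysis; 100 suffice to measure
coverage of the procedure itself); 25 seeded n = 3000 cohorts for the
rare-variant discordance scenario (chosen so the expected count of top-bin
extreme carriers is ≈ 2.8 per cohort); and 20 seeded 88-gene panels for the
expression funnel.
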