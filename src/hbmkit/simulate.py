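"""Synthetic cohorts with the statistical structure the downstream analysis assumes.

Generative model
----------------
Each of ``n_snps`` biallelic SNPs has a risk-allele frequency drawn from
``maf_range`` and a strictly positive per-allele effect size (the phenotype
decrease per copy of the risk allele). Dosages are drawn per SNP from
Binomial(2, p) — Hardy-Weinberg equilibrium, no linkage disequilibrium.
The latent phenotype of subject *i* is

    P_i = baseline - sum_j beta_j g_ij + N(0, noise_sd)

standardized against the simulated cohort. Lumbar-spine and hip Z-scores are
two noisy views of the standardized latent phenotype with within-subject
correlation ``site_correlation``, each re-standardized against the cohort, so
the sum Z-score (LS + hip) behaves like the ascertainment statistic of a real
DXA cohort. An optional rare protective variant adds a fixed shift (in SD
units) to carriers' latent phenotype; heterozygotes express the full shift
(dominance).

Missingness is injected uniformly at random (MCAR) and is flagged as NaN,
distinct from dosage 0. Phenotypes are always generated from the complete
matrix; use :func:`simulate_cohort` for the generate -> phenotype -> mask
sequence, or :func:`inject_missingness` directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, RareVariantSpec, SimulationConfig

_BASES = np.array(list("ACGT"))

# Fixed stage keys so each operation has an independent, reproducible stream
# regardless of which other operations ran before it.
_STAGE = {
    "effects": 1,
    "genotypes": 2,
    "phenotypes": 3,
    "missing": 4,
    "pedigree": 5,
    "ct": 6,
}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(_STAGE[stage],))
    return np.random.default_rng(ss)


@dataclass
class CohortBundle:
    """One simulated cohort: effect table, true/observed genotypes, subjects."""

    effects: pd.DataFrame
    genotypes_true: pd.DataFrame
    genotypes: pd.DataFrame
    subjects: pd.DataFrame


def simulate_effect_table(config: SimulationConfig) -> pd.DataFrame:
    """Draw a SNP effect table: rsid, effect/other allele, beta (> 0), MAF."""
    rng = _rng(config, "effects")
    n = config.n_snps
    rsid = [f"rs{1000001 + i}" for i in range(n)]
    eff_idx = rng.integers(0, 4, n)
    oth_idx = (eff_idx + rng.integers(1, 4, n)) % 4
    beta = config.effect_size.draw(rng, n)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, n) if lo < hi else np.full(n, lo)
    return pd.DataFrame(
        {
            "rsid": rsid,
            "effect_allele": _BASES[eff_idx],
            "other_allele": _BASES[oth_idx],
            "beta": beta,
            "maf": maf,
        }
    )


def simulate_genotypes(
    effects: pd.DataFrame,
    config: SimulationConfig,
    missing_rate: float | None = None,
) -> pd.DataFrame:
    """Draw a subjects x SNPs dosage matrix under HWE; NaN marks missing calls.

    ``missing_rate`` overrides ``config.missing_rate`` (pass 0.0 for a complete
    matrix suitable for phenotype generation).
    """
    if len(effects) == 0:
        raise ValueError("effect table is empty")
    rng = _rng(config, "genotypes")
    maf = effects["maf"].to_numpy(dtype=float)
    dosages = rng.binomial(2, maf, size=(config.n_subjects, len(effects))).astype(float)
    ids = [f"S{i + 1:04d}" for i in range(config.n_subjects)]
    matrix = pd.DataFrame(dosages, index=ids, columns=list(effects["rsid"]))
    rate = config.missing_rate if missing_rate is None else float(missing_rate)
    if rate > 0:
        matrix = inject_missingness(matrix, config, rate)
    return matrix


def inject_missingness(
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    rate: float | None = None,
) -> pd.DataFrame:
    """Mask entries uniformly at random (MCAR) as NaN; returns a copy."""
    rate = config.missing_rate if rate is None else float(rate)
    if not (0.0 <= rate < 1.0):
        raise ConfigError("missing_rate", f"must be in [0, 1), got {rate}")
    rng = _rng(config, "missing")
    values = genotypes.to_numpy(dtype=float, copy=True)
    values[rng.random(values.shape) < rate] = np.nan
    return pd.DataFrame(values, index=genotypes.index, columns=genotypes.columns)


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return values - values.mean()
    return (values - values.mean()) / sd


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    effects: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate subject records (Z-scores, carrier status) from complete dosages.

    The genotype matrix must be complete (no NaN) and its columns must match
    the effect table's rsids; phenotypes are a function of true dosages, never
    of masked ones.
    """
    if list(genotypes.columns) != list(effects["rsid"]):
        raise ValueError(
            "dimension mismatch: genotype columns do not match effect-table rsids"
        )
    g = genotypes.to_numpy(dtype=float)
    if np.isnan(g).any():
        raise ValueError(
            "genotype matrix contains missing calls; phenotypes must be generated "
            "from the complete matrix (see simulate_cohort / inject_missingness)"
        )
    rng = _rng(config, "phenotypes")
    n = g.shape[0]
    beta = effects["beta"].to_numpy(dtype=float)
    raw = config.baseline - g @ beta + rng.normal(0.0, config.noise_sd, n)
    latent = _standardize(raw)

    carrier = np.zeros(n, dtype=bool)
    if config.rare_variant is not None:
        carrier = rng.random(n) < config.rare_variant.carrier_frequency
        latent = latent + config.rare_variant.protective_effect * carrier

    rho = config.site_correlation
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    ls = _standardize(a * latent + b * rng.standard_normal(n))
    hip = _standardize(a * latent + b * rng.standard_normal(n))
    age = rng.integers(48, 81, n)

    return pd.DataFrame(
        {
            "id": list(genotypes.index),
            "age": age,
            "ls_z": ls,
            "hip_z": hip,
            "sum_z": ls + hip,
            "cohort": "SIM",
            "dna_available": True,
            "genotyped": True,
            "carrier": carrier,
            "phenotype_raw": raw,
        }
    )


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Full generate sequence: effects -> complete genotypes -> phenotypes -> mask."""
    effects = simulate_effect_table(config)
    genotypes_true = simulate_genotypes(effects, config, missing_rate=0.0)
    subjects = simulate_phenotypes(genotypes_true, effects, config)
    observed = (
        inject_missingness(genotypes_true, config)
        if config.missing_rate > 0
        else genotypes_true.copy()
    )
    return CohortBundle(
        effects=effects,
        genotypes_true=genotypes_true,
        genotypes=observed,
        subjects=subjects,
    )


def _measure_sum_z(latent: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """LS + hip measurement of a latent value on the population reference scale."""
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    ls = a * latent + b * rng.standard_normal(latent.shape)
    hip = a * latent + b * rng.standard_normal(latent.shape)
    return ls + hip


def simulate_pedigree(
    founder_carrier: bool,
    n_offspring: int,
    config: SimulationConfig,
    founder_sum_z: float | None = None,
) -> pd.DataFrame:
    """Nuclear pedigree: proband, spouse and offspring with Mendelian transmission.

    Offspring of a heterozygous carrier proband inherit the candidate variant
    with probability 1/2; carriers express the protective shift in full. Sum
    Z-scores are measured on the population reference scale (no within-family
    restandardization). Family studies start from an ascertained proband whose
    phenotype is already observed; pass ``founder_sum_z`` to record that
    observed value instead of drawing a fresh (unconditioned) one.
    """
    if n_offspring < 1:
        raise ValueError(f"n_offspring must be >= 1, got {n_offspring}")
    rng = _rng(config, "pedigree")
    spec = config.rare_variant if config.rare_variant is not None else RareVariantSpec()
    shift = spec.protective_effect
    rho = config.site_correlation

    latents = rng.standard_normal(2 + n_offspring)
    if founder_carrier:
        latents[0] += shift
    kid_carrier = (
        (rng.random(n_offspring) < 0.5) if founder_carrier else np.zeros(n_offspring, bool)
    )
    latents[2:] += shift * kid_carrier
    sum_z = _measure_sum_z(latents, rho, rng)
    if founder_sum_z is not None:
        sum_z[0] = float(founder_sum_z)

    ids = ["proband", "spouse"] + [f"child_{i + 1:02d}" for i in range(n_offspring)]
    relations = ["proband", "spouse"] + ["offspring"] * n_offspring
    carrier = np.concatenate(([founder_carrier, False], kid_carrier))
    return pd.DataFrame(
        {
            "id": ids,
            "relation": relations,
            "sum_z": sum_z,
            "carrier": np.where(carrier, "carrier", "non-carrier"),
        }
    )


def simulate_ct_panel(
    n_genes: int,
    samples: pd.DataFrame,
    trend_genes: dict[str, float],
    config: SimulationConfig,
    *,
    reference_gene: str = "B2M",
    n_replicates: int = 3,
    replicate_sd: float = 0.15,
    biological_sd: float = 0.4,
) -> pd.DataFrame:
    """Triplicate Ct panel over ``samples`` (requires columns ``id`` and ``sum_z``).

    The first gene is the designated stable reference: its true mean Ct is
    constant across samples (only replicate noise varies), so it has the
    minimum coefficient of variation by construction. Trend genes' mean Ct
    varies linearly with the sum Z-score (``trend_genes`` maps gene -> Ct
    slope per Z unit; a negative expression trend is a positive Ct slope).
    All other genes get independent per-sample biological noise.
    """
    if n_genes < 2:
        raise ValueError("panel needs at least the reference gene and one target")
    genes = [reference_gene] + [f"G{i:03d}" for i in range(2, n_genes + 1)]
    unknown = set(trend_genes) - set(genes)
    if unknown:
        raise ValueError(f"trend genes not in panel: {sorted(unknown)}")
    if reference_gene in trend_genes:
        raise ValueError("the reference gene cannot be a trend gene")

    rng = _rng(config, "ct")
    sample_ids = list(samples["id"])
    sum_z = samples["sum_z"].to_numpy(dtype=float)
    n_samples = len(sample_ids)

    base = rng.uniform(22.0, 30.0, n_genes)
    base[0] = 21.0  # reference gene: abundant transcript, low Ct
    slopes = np.array([trend_genes.get(g, 0.0) for g in genes])
    means = base[:, None] + slopes[:, None] * sum_z[None, :]
    bio = rng.normal(0.0, biological_sd, size=(n_genes, n_samples))
    if biological_sd > 0 and n_samples >= 2:
        # normalize each gene's sample offsets to mean 0, sd exactly
        # biological_sd: every non-reference gene then varies across samples
        # by at least the biological scatter, making the designated
        # reference's minimal CV structural rather than probabilistic.
        bio -= bio.mean(axis=1, keepdims=True)
        sd = bio.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        bio *= biological_sd / sd
    bio[0, :] = 0.0  # the reference gene's true level is constant
    means = means + bio
    rep_noise = rng.normal(0.0, replicate_sd, size=(n_genes, n_samples, n_replicates))
    # Center each triplicate so replicate averaging recovers the designed
    # per-sample mean exactly; the reference gene's cross-sample CV is then
    # zero by construction (minimal among all genes), while replicate-level
    # scatter is preserved.
    rep_noise -= rep_noise.mean(axis=2, keepdims=True)
    ct = means[:, :, None] + rep_noise

    records = {
        "gene": np.repeat(genes, n_samples * n_replicates),
        "sample": np.tile(np.repeat(sample_ids, n_replicates), n_genes),
        "replicate": np.tile(np.arange(1, n_replicates + 1), n_genes * n_samples),
        "ct": ct.ravel(),
    }
    return pd.DataFrame(records)
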