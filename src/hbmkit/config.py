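"""Configuration for the synthetic-cohort generator.

The generator emulates a postmenopausal DXA-scanned cohort: ~1000 subjects
genotyped at a few dozen biallelic SNPs in Hardy-Weinberg equilibrium, each
risk allele decreasing bone density additively by a small amount, Gaussian
environmental noise, two correlated skeletal-site Z-scores per subject, and
an optional rare, large-effect protective variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import yaml


class ConfigError(ValueError):
    """A configuration field is outside its documented range."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class EffectSizeSpec:
    """Distribution of per-allele effect sizes (phenotype decrease per risk allele).

    ``uniform`` draws from U(low, high); ``lognormal`` from LogNormal(mean, sigma).
    Effect sizes are oriented so that the effect allele decreases the phenotype,
    hence they are strictly positive.
    """

    distribution: str = "uniform"
    params: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.04, "high": 0.12}
    )

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "uniform":
            lo = float(self.params["low"])
            hi = float(self.params["high"])
            if not (0.0 < lo <= hi):
                raise ConfigError("effect_size", f"uniform bounds must satisfy 0 < low <= high, got ({lo}, {hi})")
            return rng.uniform(lo, hi, n) if lo < hi else np.full(n, lo)
        if self.distribution == "lognormal":
            mean = float(self.params.get("mean", -2.8))
            sigma = float(self.params.get("sigma", 0.4))
            if sigma <= 0:
                raise ConfigError("effect_size", f"lognormal sigma must be > 0, got {sigma}")
            return rng.lognormal(mean, sigma, n)
        raise ConfigError("effect_size", f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class RareVariantSpec:
    """A rare, fully penetrant protective variant.

    ``protective_effect`` is the additive shift (in latent-phenotype SD units)
    that a heterozygous carrier expresses; dominance is assumed, so one copy
    expresses the full shift.
    """

    carrier_frequency: float = 0.02
    protective_effect: float = 3.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Identical config + seed produce bit-identical cohorts, genotype matrices,
    pedigrees and Ct panels.
    """

    n_subjects: int = 1001
    n_snps: int = 54
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_size: EffectSizeSpec = field(default_factory=EffectSizeSpec)
    noise_sd: float = 0.9
    site_correlation: float = 0.6
    missing_rate: float = 0.02
    baseline: float = 0.0
    rare_variant: RareVariantSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects", f"must be >= 1, got {self.n_subjects}")
        if self.n_snps < 1:
            raise ConfigError("n_snps", f"must be >= 1, got {self.n_snps}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range", f"must lie within (0, 0.5] with low <= high, got {self.maf_range}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd", f"must be > 0, got {self.noise_sd}")
        if not (0.0 <= self.site_correlation < 1.0):
            raise ConfigError("site_correlation", f"must be in [0, 1), got {self.site_correlation}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate", f"must be in [0, 1), got {self.missing_rate}")
        if self.rare_variant is not None:
            cf = self.rare_variant.carrier_frequency
            if not (0.0 < cf < 1.0):
                raise ConfigError("rare_variant.carrier_frequency", f"must be in (0, 1), got {cf}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(float(v) for v in d["maf_range"])
        if "effect_size" in d and isinstance(d["effect_size"], Mapping):
            es = dict(d["effect_size"])
            dist = es.pop("distribution", "uniform")
            params = es.pop("params", es)
            d["effect_size"] = EffectSizeSpec(distribution=dist, params=dict(params))
        rv = d.get("rare_variant")
        if rv is not None and isinstance(rv, Mapping):
            d["rare_variant"] = RareVariantSpec(**{k: float(v) for k, v in rv.items()})
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)
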