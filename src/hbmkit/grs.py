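"""Effect-size-weighted genetic risk score (GRS) with imputation and binning.

The score of one SNP is dosage x beta: homozygotes for the risk allele score
2x the effect size, heterozygotes 1x, homozygotes for the alternative allele
zero. Missing genotypes are replaced by the mean of the corresponding SNP
scores in a reference cohort (mean imputation, which attenuates group
variance but preserves the mean). Per-subject SNP scores are summed into a
raw score (phenotype units) and normalized by the mean effect size of the
SNP panel, putting the score on an effective-risk-allele-count scale in
[0, 2 x n_snps]. Normalized scores are sorted into equal-width bins for the
histogram/bin-mean display, and the bin-level Pearson correlation between
bin midpoint and mean phenotype summarizes the additive-architecture trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BIN_WIDTH = 4.0


def snp_score(dosage, beta):
    """Per-SNP risk score: dosage x effect size. Missing dosages are rejected.

    Mean imputation must happen upstream (see :func:`impute_missing_scores`);
    a NaN reaching this operation is a pipeline error, not a silent zero.
    """
    d = np.asarray(dosage, dtype=float)
    b = np.asarray(beta, dtype=float)
    if np.isnan(d).any():
        raise ValueError("missing dosage reached snp_score; impute first")
    if (b <= 0).any():
        raise ValueError("effect sizes must be strictly positive (risk-allele orientation)")
    out = d * b
    return float(out) if out.ndim == 0 else out


def impute_missing_scores(
    genotypes: pd.DataFrame,
    effects: pd.DataFrame,
    reference: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Score every subject x SNP cell, mean-imputing missing cells from a reference.

    A missing cell's score is the mean of that SNP's scores over non-missing
    reference subjects. Returns (score table, per-subject imputation counts).
    """
    rsids = list(effects["rsid"])
    if list(genotypes.columns) != rsids:
        genotypes = genotypes[rsids]
    missing_cols = [r for r in rsids if r not in reference.columns]
    if missing_cols:
        raise ValueError(f"reference cohort lacks SNPs: {missing_cols}")
    beta = effects.set_index("rsid")["beta"]

    ref = reference[rsids]
    n_called = ref.notna().sum(axis=0)
    dead = n_called.index[n_called == 0].tolist()
    if dead:
        raise ValueError(f"SNP entirely missing in reference cohort: {dead}")
    ref_mean_score = ref.mean(axis=0, skipna=True) * beta

    scores = genotypes.mul(beta, axis=1)
    n_imputed = genotypes.isna().sum(axis=1)
    scores = scores.fillna(ref_mean_score)
    return scores, n_imputed


def global_score(score_table: pd.DataFrame) -> pd.Series:
    """Sum of per-SNP scores per subject (raw score, phenotype units)."""
    if score_table.isna().any().any():
        raise ValueError("score table contains NaN; impute before summing")
    return score_table.sum(axis=1)


def mean_effect_size(effects: pd.DataFrame) -> float:
    if len(effects) == 0:
        raise ValueError("effect table is empty")
    return float(effects["beta"].mean())


def normalize_score(raw_score, effects: pd.DataFrame):
    """Raw score divided by the panel's mean effect size (allele-count scale)."""
    mb = mean_effect_size(effects)
    out = np.asarray(raw_score, dtype=float) / mb
    if np.ndim(raw_score) == 0:
        return float(out)
    if isinstance(raw_score, pd.Series):
        return pd.Series(out, index=raw_score.index)
    return out


@dataclass
class BinAssignment:
    """Bin membership of each scored subject plus the shared edges/labels."""

    index: pd.Series  # 1..n_bins per subject
    edges: np.ndarray  # length n_bins + 1, strictly increasing
    labels: list[str]  # per bin, e.g. "44-48"
    n_clamped: int = 0

    @property
    def label(self) -> pd.Series:
        mapping = {i + 1: lab for i, lab in enumerate(self.labels)}
        return self.index.map(mapping)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def default_bin_edges(scores, n_bins: int = 5, width: float = BIN_WIDTH) -> np.ndarray:
    """Equal-width edges at multiples of ``width``, centered on the median's bin.

    The window is anchored so the bin containing the cohort median sits in the
    middle of the ``n_bins`` window; scores outside the window are clamped to
    the terminal bins at assignment time.
    """
    scores = np.asarray(scores, dtype=float)
    median = float(np.median(scores))
    anchor = np.floor(median / width) * width
    start = anchor - width * ((n_bins - 1) // 2)
    return start + width * np.arange(n_bins + 1)


def assign_bins(
    scores,
    n_bins: int = 5,
    edges=None,
    warn_clamp: bool = True,
) -> BinAssignment:
    """Sort normalized scores into bins (left-closed, right-open; last closed).

    With no explicit edges, a width-4 window anchored at multiples of 4 around
    the cohort median is used. Scores outside the supplied edges are clamped
    to the terminal bins with a warning.
    """
    values = pd.Series(scores, dtype=float)
    if edges is None:
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        edges = default_bin_edges(values.to_numpy(), n_bins=n_bins)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 3:
        raise ValueError("edges must be a 1-D array defining >= 2 bins")
    if not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be strictly increasing")
    n_bins = len(edges) - 1

    # Inner edges only: anything below the window lands in bin 1, anything at
    # or above the last inner edge in the final bin (so the maximum score and
    # clamped values are never lost).
    idx = np.digitize(values.to_numpy(), edges[1:-1], right=False) + 1
    n_clamped = int(((values < edges[0]) | (values > edges[-1])).sum())
    if n_clamped and warn_clamp:
        warnings.warn(
            f"{n_clamped} score(s) outside [{edges[0]:g}, {edges[-1]:g}] clamped "
            "to terminal bins",
            stacklevel=2,
        )
    labels = [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(n_bins)]
    return BinAssignment(
        index=pd.Series(idx, index=values.index, name="bin_index"),
        edges=edges,
        labels=labels,
        n_clamped=n_clamped,
    )


def bin_summary(assignment: BinAssignment, phenotype) -> pd.DataFrame:
    """Per-bin count, mean phenotype and standard error of the mean.

    Empty bins keep count 0 with NaN-marked mean/se; singleton bins have a
    NaN se (sd undefined at n=1).
    """
    phen = pd.Series(phenotype, dtype=float)
    if len(phen) != len(assignment.index):
        raise ValueError("phenotype and bin assignment lengths differ")
    phen = pd.Series(phen.to_numpy(), index=assignment.index.index)
    rows = []
    for b in range(1, len(assignment.labels) + 1):
        values = phen[assignment.index == b]
        count = int(len(values))
        mean = float(values.mean()) if count else np.nan
        se = float(values.std(ddof=1) / np.sqrt(count)) if count > 1 else np.nan
        rows.append(
            {
                "bin_index": b,
                "bin_label": assignment.labels[b - 1],
                "midpoint": assignment.midpoints[b - 1],
                "count": count,
                "mean_phenotype": mean,
                "se_phenotype": se,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BinCorrelation:
    r: float
    p_value: float
    r_squared: float
    n_bins_used: int


def bin_correlation(summary: pd.DataFrame) -> BinCorrelation:
    """Pearson correlation between bin midpoints and bin mean phenotypes.

    Uses the conventional two-sided t test on n-2 degrees of freedom, n being
    the number of non-empty bins; requires at least three of them.
    """
    used = summary.loc[summary["count"] > 0]
    if len(used) < 3:
        raise ValueError("bin correlation needs >= 3 non-empty bins")
    x = used["midpoint"].to_numpy(dtype=float)
    y = used["mean_phenotype"].to_numpy(dtype=float)
    if np.std(y) == 0 or np.std(x) == 0:
        return BinCorrelation(np.nan, np.nan, np.nan, len(used))
    r, p = stats.pearsonr(x, y)
    return BinCorrelation(float(r), float(p), float(r) ** 2, len(used))


@dataclass
class ScoredCohort:
    """Per-subject risk-score results plus the shared bin structure."""

    table: pd.DataFrame  # id, raw_score, normalized_score, n_imputed, bin_index, bin_label
    assignment: BinAssignment
    mean_beta: float
    effects: pd.DataFrame  # panel actually used (after exclusions)


def score_cohort(
    genotypes: pd.DataFrame,
    effects: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    exclude: tuple[str, ...] = (),
    n_bins: int = 5,
    edges=None,
) -> ScoredCohort:
    """Full scoring pipeline: exclude SNPs, impute, sum, normalize, bin.

    ``reference`` supplies the imputation means and, when ``edges`` is None,
    anchors nothing further (edges come from the scored cohort itself; pass
    the reference cohort's edges explicitly to bin a subgroup on its scale).
    ``exclude`` drops SNPs before scoring and the panel mean effect size is
    recomputed on the retained SNPs.
    """
    if exclude:
        effects = effects.loc[~effects["rsid"].isin(exclude)].reset_index(drop=True)
    if len(effects) == 0:
        raise ValueError("no SNPs left after exclusions")
    rsids = list(effects["rsid"])
    genotypes = genotypes[rsids]
    reference = genotypes if reference is None else reference[rsids]

    scores, n_imputed = impute_missing_scores(genotypes, effects, reference)
    raw = global_score(scores)
    normalized = normalize_score(raw, effects)
    assignment = assign_bins(normalized, n_bins=n_bins, edges=edges)
    table = pd.DataFrame(
        {
            "id": list(genotypes.index),
            "raw_score": raw.to_numpy(),
            "normalized_score": normalized.to_numpy(),
            "n_imputed": n_imputed.to_numpy(),
            "bin_index": assignment.index.to_numpy(),
            "bin_label": assignment.label.to_numpy(),
        }
    )
    return ScoredCohort(
        table=table,
        assignment=assignment,
        mean_beta=mean_effect_size(effects),
        effects=effects,
    )
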