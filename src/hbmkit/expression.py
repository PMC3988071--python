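"""qPCR expression screen: reference gene, ddCt-free relative expression,
two-fold candidate funnel, expression-vs-Z trend and fold outliers.

Quantification uses the delta-Ct method with a perfect-doubling efficiency:
expression = 2^-(meanCt_gene - meanCt_reference) per sample, triplicate Ct
values averaged first. The reference gene is the candidate whose per-sample
mean Ct has the minimum coefficient of variation across samples (reference
stability is conventionally judged on the Ct scale). The candidate screen
keeps genes whose case/control mean-expression ratio is at least ``fold``
in either direction; single-case outliers are flagged at a (default 5-fold)
deviation from the control mean. The expression-vs-sum-Z trend is an
ordinary least-squares fit reported as slope/intercept/R^2 without a
p-value: at these sample sizes the regression assumptions cannot be
verified, so only the descriptive fit is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def mean_ct(panel: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean Ct as a genes x samples table."""
    required = {"gene", "sample", "ct"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"Ct panel missing columns: {sorted(missing)}")
    if (panel["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return panel.pivot_table(index="gene", columns="sample", values="ct", aggfunc="mean")


def select_reference_gene(panel: pd.DataFrame, candidates: list[str]) -> str:
    """Candidate with minimal cross-sample CV (sd/mean) of replicate-mean Ct.

    Candidates not measured in every sample are excluded with a warning; ties
    break toward the lexicographically first gene label, with a warning.
    """
    table = mean_ct(panel)
    unknown = [g for g in candidates if g not in table.index]
    if unknown:
        raise ValueError(f"candidate genes not in panel: {unknown}")
    cvs: dict[str, float] = {}
    for gene in candidates:
        row = table.loc[gene]
        if row.isna().any():
            warnings.warn(f"reference candidate {gene} missing in some samples; excluded",
                          stacklevel=2)
            continue
        cvs[gene] = float(row.std(ddof=1) / row.mean())
    if not cvs:
        raise ValueError("no valid reference candidate (all have missing samples)")
    best = min(cvs.values())
    tied = sorted(g for g, cv in cvs.items() if cv == best)
    if len(tied) > 1:
        warnings.warn(f"reference CV tie between {tied}; choosing {tied[0]}", stacklevel=2)
    return tied[0]


def relative_expression(panel: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Reference-normalized expression 2^-(dCt) as a genes x samples table.

    Adding any constant to every Ct of a sample cancels out, so plate-level
    sample offsets do not affect the result. Missing gene x sample cells stay
    NaN-marked.
    """
    table = mean_ct(panel)
    if reference not in table.index:
        raise ValueError(f"reference gene {reference!r} not in panel")
    ref_row = table.loc[reference]
    if ref_row.isna().any():
        raise ValueError("reference gene must be measured in every sample")
    return 2.0 ** -(table.sub(ref_row, axis=1))


@dataclass
class ScreenResult:
    selected: list[str]
    unscreenable: list[str]
    table: pd.DataFrame  # gene, case_mean, control_mean, ratio, selected


def fold_change_screen(
    expression: pd.DataFrame,
    cases: list[str],
    controls: list[str],
    threshold: float = 2.0,
    exclude: tuple[str, ...] = (),
) -> ScreenResult:
    """Keep genes with >= ``threshold``-fold case/control mean difference.

    The rule is symmetric: a gene passing at ratio r passes at 1/r. Genes
    with an undefined ratio (zero or missing control mean) are reported
    unscreenable rather than silently dropped.
    """
    if threshold <= 1:
        raise ValueError("fold threshold must be > 1")
    if not cases or not controls:
        raise ValueError("need at least one case and one control sample")
    expr = expression.drop(index=[g for g in exclude if g in expression.index])
    case_mean = expr[list(cases)].mean(axis=1)
    control_mean = expr[list(controls)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = case_mean / control_mean
    ratio[(control_mean <= 0) | control_mean.isna() | case_mean.isna()] = np.nan
    selected_mask = (ratio >= threshold) | (ratio <= 1.0 / threshold)
    table = pd.DataFrame(
        {
            "gene": expr.index,
            "case_mean": case_mean.to_numpy(),
            "control_mean": control_mean.to_numpy(),
            "ratio": ratio.to_numpy(),
            "selected": selected_mask.fillna(False).to_numpy(),
        }
    ).reset_index(drop=True)
    return ScreenResult(
        selected=sorted(table.loc[table["selected"], "gene"]),
        unscreenable=sorted(table.loc[table["ratio"].isna(), "gene"]),
        table=table,
    )


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def expression_z_trend(expression_row: pd.Series, sum_z: pd.Series) -> TrendFit:
    """OLS of one gene's expression on sum Z-score; descriptive fit only."""
    joined = pd.concat([expression_row.rename("expr"), sum_z.rename("z")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("trend fit needs >= 3 samples with expression and sum Z")
    fit = stats.linregress(joined["z"], joined["expr"])
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=len(joined),
    )


def outlier_flag(
    expression_row: pd.Series,
    case: str,
    controls: list[str],
    fold: float = 5.0,
) -> str | None:
    """'up'/'down' when one case deviates >= ``fold``-fold from the control mean."""
    if not controls:
        raise ValueError("need at least one control sample")
    control_mean = float(expression_row[list(controls)].mean())
    value = float(expression_row[case])
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise ValueError("control mean undefined; gene unscreenable")
    if value >= fold * control_mean:
        return "up"
    if value <= control_mean / fold:
        return "down"
    return None
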