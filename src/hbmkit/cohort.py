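"""Subject tables, extreme-phenotype ascertainment and prevalence.

A subject record carries lumbar-spine and hip (femoral) DXA Z-scores, their
sum (the high-bone-mass ascertainment statistic), cohort label and sample
availability flags. ``hip_z`` is used interchangeably for "total femoral
neck" and "hip" Z-scores. A packaged 16-row fixture reproduces the study
cohort table of the source dataset (cases HBM1..HBM16).
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

SUBJECT_COLUMNS = [
    "id",
    "age",
    "ls_z",
    "hip_z",
    "sum_z",
    "cohort",
    "dna_available",
    "genotyped",
]

_FLAGS = ("dna_available", "genotyped")

#: Tolerance for the sum == LS + hip consistency check; printed tables are
#: rounded to one decimal, so components may disagree with the sum by < 0.05.
SUM_Z_TOLERANCE = 0.05


def compute_sum_z(ls_z, hip_z):
    """Sum Z-score: lumbar-spine Z plus hip Z. Inputs must be finite."""
    ls = np.asarray(ls_z, dtype=float)
    hip = np.asarray(hip_z, dtype=float)
    if not (np.isfinite(ls).all() and np.isfinite(hip).all()):
        raise ValueError("Z-scores must be finite to compute a sum Z-score")
    total = ls + hip
    return float(total) if total.ndim == 0 else total


def check_sum_consistency(table: pd.DataFrame, tol: float = SUM_Z_TOLERANCE) -> pd.Series:
    """Flag rows whose stated sum_z disagrees with ls_z + hip_z beyond ``tol``.

    Returns a boolean Series (True = consistent) and warns when any row fails.
    """
    diff = (table["sum_z"] - (table["ls_z"] + table["hip_z"])).abs()
    ok = diff <= tol
    if (~ok).any():
        bad = table.loc[~ok, "id"].tolist()
        warnings.warn(
            f"sum_z inconsistent with ls_z + hip_z beyond {tol} for: {bad}",
            stacklevel=2,
        )
    return ok


def ascertain_hbm(table: pd.DataFrame, threshold: float = 4.0) -> pd.DataFrame:
    """Rows with sum Z-score >= threshold, original order preserved.

    The inclusive criterion follows the cohort definition (sum Z equal to or
    greater than four). If ``sum_z`` is absent it is computed from components.
    """
    if len(table) == 0:
        return table.copy()
    if "sum_z" in table.columns:
        sum_z = table["sum_z"]
    else:
        sum_z = compute_sum_z(table["ls_z"], table["hip_z"])
    return table.loc[np.asarray(sum_z) >= threshold].copy()


def prevalence(n_cases: int, n_scanned: int) -> float:
    """Percentage of scanned individuals meeting the case criterion."""
    if n_scanned <= 0:
        raise ValueError("n_scanned must be > 0")
    if not (0 <= n_cases <= n_scanned):
        raise ValueError("n_cases must lie in [0, n_scanned]")
    return 100.0 * n_cases / n_scanned


def format_prevalence(n_cases: int, n_scanned: int) -> str:
    """Prevalence rounded half-up to two decimals, e.g. 10/1600 -> '0.63%'."""
    pct = Decimal(prevalence(n_cases, n_scanned)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return f"{pct}%"


def filter_available(table: pd.DataFrame, flag: str) -> pd.DataFrame:
    """Subset of subjects with an availability flag set (dna_available / genotyped)."""
    if flag not in _FLAGS:
        raise ValueError(f"unknown availability flag {flag!r}; expected one of {_FLAGS}")
    return table.loc[table[flag].astype(bool)].copy()


def write_subjects(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for flag in _FLAGS:
        if flag in out.columns:
            out[flag] = out[flag].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_subjects(path, check: bool = True) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for flag in _FLAGS:
        if flag in table.columns:
            table[flag] = table[flag].astype(bool)
    if "id" in table.columns and table["id"].duplicated().any():
        dup = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate subject ids: {dup}")
    if "sum_z" not in table.columns and {"ls_z", "hip_z"} <= set(table.columns):
        table["sum_z"] = compute_sum_z(table["ls_z"], table["hip_z"])
    elif check and {"sum_z", "ls_z", "hip_z"} <= set(table.columns):
        check_sum_consistency(table)
    return table


def load_study_cases() -> pd.DataFrame:
    """The packaged 16-case study table (Z-scores, age, cohort, availability)."""
    path = resources.files("hbmkit.data") / "table1.tsv"
    with resources.as_file(path) as p:
        return read_subjects(p)
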