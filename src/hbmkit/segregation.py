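"""Dominant-model cosegregation of a candidate variant in nuclear pedigrees.

A pedigree is a small table of members: id, relation, sum Z-score (possibly
unknown) and carrier status in {carrier, non-carrier, unknown}. A member is
affected when the sum Z-score meets the high-bone-mass threshold (default 4,
shared with the cohort module). Under a fully penetrant dominant model the
variant cosegregates when every known carrier is affected and every known
non-carrier is unaffected; members missing either datum are uninformative.
Discordance counts are reported so partial-penetrance judgments remain
possible downstream. Two packaged fixtures reproduce the study's pedigrees:
a carrier trio (proband + affected carrier daughter + unaffected non-carrier
son) and a phenotype-only family whose candidate variant was never
identified (all carrier statuses unknown, hence uninformative).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
UNINFORMATIVE = "uninformative"

_CARRIER_STATES = {"carrier": True, "non-carrier": False, "unknown": None}


@dataclass
class CosegregationResult:
    verdict: str
    n_concordant: int
    n_discordant: int
    members: pd.DataFrame  # id, relation, sum_z, carrier, affected, informative, concordant


def _parse_carrier(value) -> bool | None:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    key = str(value).strip().lower()
    if key in _CARRIER_STATES:
        return _CARRIER_STATES[key]
    raise ValueError(f"unknown carrier status {value!r}")


def cosegregation_check(pedigree: pd.DataFrame, threshold: float = 4.0) -> CosegregationResult:
    """Assess dominant, fully penetrant cosegregation of variant and phenotype.

    Verdict is ``consistent`` iff every informative member is concordant
    (carrier <=> affected), ``inconsistent`` if any is discordant, and
    ``uninformative`` with fewer than two informative members. The verdict is
    invariant under member reordering.
    """
    members = pedigree.copy().reset_index(drop=True)
    carrier = members["carrier"].map(_parse_carrier)
    if "affected" in members.columns:
        affected = members["affected"].map(
            lambda v: None if (v is None or (isinstance(v, float) and np.isnan(v))) else bool(v)
        )
    else:
        sum_z = pd.to_numeric(members["sum_z"], errors="coerce")
        affected = sum_z.map(lambda z: None if np.isnan(z) else bool(z >= threshold))

    informative = carrier.notna() & affected.notna()
    concordant = pd.Series([None] * len(members), dtype=object)
    concordant[informative] = [
        bool(c) == bool(a) for c, a in zip(carrier[informative], affected[informative])
    ]

    n_informative = int(informative.sum())
    n_concordant = int(sum(bool(v) for v in concordant[informative]))
    n_discordant = n_informative - n_concordant
    if n_informative < 2:
        verdict = UNINFORMATIVE
    elif n_discordant:
        verdict = INCONSISTENT
    else:
        verdict = CONSISTENT

    members = members.assign(
        affected=affected, informative=informative, concordant=concordant
    )
    return CosegregationResult(
        verdict=verdict,
        n_concordant=n_concordant,
        n_discordant=n_discordant,
        members=members,
    )


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"id", "relation", "sum_z", "carrier"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
    df["carrier"] = df["carrier"].fillna("unknown")
    return df


def _load_fixture(name: str) -> pd.DataFrame:
    path = resources.files("hbmkit.data") / name
    with resources.as_file(path) as p:
        return read_pedigree(p)


def load_carrier_trio_pedigree() -> pd.DataFrame:
    """Proband trio with genotyped candidate variant (cosegregation-positive)."""
    return _load_fixture("fig1b_pedigree.tsv")


def load_unresolved_family_pedigree() -> pd.DataFrame:
    """Phenotype-segregating family whose candidate variant is unidentified."""
    return _load_fixture("fig2c_pedigree.tsv")
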