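"""Tabular and VCF input/output shared across the toolkit.

All tables are plain TSV. The genotype matrix is wide (subjects x rsids) with
``NA`` for missing calls. A minimal biallelic VCF dialect (GT field only,
diploid, unphased, ALT = effect allele) is provided for interoperability;
reading goes through cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_effects(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, sep="\t", index=False)


def read_effects(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"rsid", "effect_allele", "other_allele", "beta", "maf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"effect table missing columns: {sorted(missing)}")
    return df


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    out = genotypes.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])
    return df.astype(float)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_ct_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_ct_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct panel missing columns: {sorted(missing)}")
    return df


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=hbmkit
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(genotypes: pd.DataFrame, effects: pd.DataFrame, path) -> None:
    """Write dosages as a minimal unphased diploid VCF (ALT = effect allele).

    A dosage d in {0, 1, 2} becomes a GT with d copies of the ALT allele;
    missing becomes ``./.``.
    """
    effects = effects.set_index("rsid").loc[list(genotypes.columns)]
    gt_by_dosage = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = [_VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(map(str, genotypes.index))]
    for pos, (rsid, row) in enumerate(effects.iterrows(), start=1):
        calls = [
            "./." if np.isnan(d) else gt_by_dosage[float(d)]
            for d in genotypes[rsid].to_numpy(dtype=float)
        ]
        lines.append(
            f"1\t{pos}\t{rsid}\t{row['other_allele']}\t{row['effect_allele']}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read the minimal dialect back into a dosage matrix (NaN for missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rsids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        rsids.append(variant.ID)
        dosage = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            dosage[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        columns.append(dosage)
    vcf.close()
    return pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=samples,
        columns=rsids,
    )
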