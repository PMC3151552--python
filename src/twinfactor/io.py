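"""Delimited-text I/O for pedigrees, phenotypes, genotypes and QC/association
reports.

Formats: a PLINK-FAM-like pedigree extended with role and zygosity columns;
a wide phenotype table (one column per occasion plus ``age_<occasion>``
columns); a dosage matrix (individuals x SNPs, ``NA`` = missing call).
All tables are tab-separated and round-trip losslessly through pandas.
A minimal VCF importer converts GT fields to minor-allele dosage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_pedigree", "write_pedigree", "read_phenotypes", "write_phenotypes",
    "read_genotypes", "write_genotypes", "genotypes_from_vcf",
    "write_table", "read_table",
]

_PED_COLS = ["fid", "iid", "father", "mother", "sex", "role", "zygosity"]


def _check_exists(path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return path


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(_check_exists(path), sep="\t", dtype=str, na_filter=False)
    missing = [c for c in _PED_COLS if c not in ped.columns]
    if missing:
        raise ValueError(f"pedigree file {path} lacks columns {missing}")
    dup = ped["iid"][ped["iid"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate individual IDs in pedigree: {list(dup)[:5]}")
    return ped[_PED_COLS]


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped[_PED_COLS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(_check_exists(path), sep="\t", index_col="iid",
                     na_values=["NA"])
    return df


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", na_rep="NA", index_label="iid")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(_check_exists(path), sep="\t", index_col="iid",
                     na_values=["NA"])
    for col in df.columns:
        vals = df[col].dropna()
        if not vals.isin([0, 1, 2]).all():
            raise ValueError(f"non-integral dosage in column {col} of {path}")
    return df.astype(float)


def write_genotypes(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, sep="\t", na_rep="NA", index_label="iid",
                float_format="%.0f")


def genotypes_from_vcf(path) -> pd.DataFrame:
    """Dosage matrix from a VCF's GT fields (``./.`` = missing).

    Dosages count the ALT allele; re-orient downstream via
    :func:`twinfactor.qc.maf` if ALT is the major allele.
    """
    from cyvcf2 import VCF  # optional dependency (install extra "vcf")

    vcf = VCF(str(_check_exists(path)))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for var in vcf:
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        gts = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dosage = np.select([gts == 0, gts == 1, gts == 3],
                           [0.0, 1.0, 2.0], default=np.nan)
        data[name] = dosage
    out = pd.DataFrame(data, index=samples)
    out.index.name = "iid"
    return out


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(_check_exists(path), sep="\t", index_col=0,
                       na_values=["NA"])
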