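"""Genotype quality control: allele frequencies, Hardy-Weinberg tests,
Mendelian error checks and unique-genotype accounting.

MZ co-twins carry one genotype between them; frequency and HWE
computations therefore deduplicate complete MZ pairs (keeping the first
co-twin by individual-ID sort) unless asked otherwise.  SNPs failing HWE
are flagged, not excluded — consistencies across SNPs in a gene would
otherwise be overlooked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import TWIN_ROLES

__all__ = [
    "maf", "hwe_test", "hwe_exact_test", "mendelian_check",
    "unique_genotype_count", "code_recessive", "qc_summary",
]


def _mz_dedup_index(ped: pd.DataFrame, geno: pd.DataFrame) -> pd.Index:
    """Index of individuals with each fully-genotyped MZ pair counted once."""
    drop = set()
    twins = ped[(ped["zygosity"] == "MZ") & ped["role"].isin(TWIN_ROLES)]
    for _, grp in twins.groupby("fid"):
        iids = sorted(grp["iid"])
        if len(iids) == 2 and all(i in geno.index for i in iids):
            drop.add(iids[1])  # deterministic: keep first co-twin by ID sort
    return geno.index[~geno.index.isin(drop)]


def _observed(geno: pd.DataFrame, snp: str, ped: pd.DataFrame | None,
              dedup_mz: bool) -> np.ndarray:
    idx = _mz_dedup_index(ped, geno) if (dedup_mz and ped is not None) else geno.index
    g = geno.loc[idx, snp].to_numpy(dtype=float)
    return g[~np.isnan(g)]


def maf(geno: pd.DataFrame, snp: str, ped: pd.DataFrame | None = None,
        dedup_mz: bool = True) -> float:
    """Minor-allele frequency from observed dosages.

    Returns min(f, 1-f) of the counted allele, so the value is always the
    minor-allele frequency regardless of orientation.
    """
    g = _observed(geno, snp, ped, dedup_mz)
    if g.size == 0:
        raise ValueError(f"all genotypes missing for {snp}")
    f = g.sum() / (2.0 * g.size)
    return min(f, 1.0 - f)


def hwe_test(geno: pd.DataFrame, snp: str, ped: pd.DataFrame | None = None,
             dedup_mz: bool = True) -> tuple[float, float]:
    """1-df chi-square goodness of fit against p^2 : 2pq : q^2 proportions."""
    g = _observed(geno, snp, ped, dedup_mz)
    counts = np.array([(g == k).sum() for k in (0, 1, 2)], dtype=float)
    n = counts.sum()
    q = (counts[1] + 2 * counts[2]) / (2 * n)
    if q in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: in HWE by convention
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(geno: pd.DataFrame, snp: str, ped: pd.DataFrame | None = None,
                   dedup_mz: bool = True) -> float:
    """Exact Hardy-Weinberg p-value (sum of probabilities of heterozygote
    counts no more likely than the observed one, conditional on allele
    counts)."""
    g = _observed(geno, snp, ped, dedup_mz)
    n_het = int((g == 1).sum())
    n_hom_min = int(min((g == 0).sum(), (g == 2).sum()))
    rare = 2 * n_hom_min + n_het
    n = g.size
    if rare == 0 or rare == 2 * n:
        return 1.0
    # recurrence over possible heterozygote counts at fixed allele counts
    het_vals = range(rare % 2, rare + 1, 2)
    logp = {}
    for h in het_vals:
        a = (rare - h) // 2
        b = n - a - h
        logp[h] = (math.lgamma(n + 1) - math.lgamma(a + 1) - math.lgamma(h + 1)
                   - math.lgamma(b + 1) + h * math.log(2)
                   + math.lgamma(rare + 1) + math.lgamma(2 * n - rare + 1)
                   - math.lgamma(2 * n + 1))
    mx = max(logp.values())
    probs = {h: math.exp(v - mx) for h, v in logp.items()}
    total = sum(probs.values())
    obs = probs[n_het]
    return min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total)


def mendelian_check(ped: pd.DataFrame, geno: pd.DataFrame) -> list[tuple]:
    """List (fid, iid, snp) of transmission-impossible offspring genotypes
    and MZ genotype discordances."""
    errors = []
    iid_set = set(geno.index)
    ped_i = ped.set_index("iid")
    for snp in geno.columns:
        g = geno[snp]
        for _, row in ped.iterrows():
            if row.father == "0" or row.iid not in iid_set:
                continue
            gf = g.get(row.father, np.nan)
            gm = g.get(row.mother, np.nan)
            gc = g.get(row.iid, np.nan)
            if np.isnan(gc) or np.isnan(gf) or np.isnan(gm):
                continue
            lo = int(gf == 2) + int(gm == 2)
            hi = 2 - int(gf == 0) - int(gm == 0)
            if not lo <= gc <= hi:
                errors.append((row.fid, row.iid, snp))
        # MZ discordance
        twins = ped[(ped["zygosity"] == "MZ") & ped["role"].isin(TWIN_ROLES)]
        for fid, grp in twins.groupby("fid"):
            iids = sorted(grp["iid"])
            if len(iids) != 2:
                continue
            g1, g2 = g.get(iids[0], np.nan), g.get(iids[1], np.nan)
            if not np.isnan(g1) and not np.isnan(g2) and g1 != g2:
                errors.append((fid, iids[1], snp))
    return errors


def unique_genotype_count(ped: pd.DataFrame, geno: pd.DataFrame, sex: str) -> int:
    """Genotyped individuals of ``sex`` minus one per fully-genotyped MZ pair."""
    ped_sex = ped[ped["sex"] == sex]
    genotyped = geno.dropna(how="all")
    n = int(ped_sex["iid"].isin(genotyped.index).sum())
    twins = ped_sex[(ped_sex["zygosity"] == "MZ") & ped_sex["role"].isin(TWIN_ROLES)]
    pairs = 0
    for _, grp in twins.groupby("fid"):
        if len(grp) == 2 and grp["iid"].isin(genotyped.index).all():
            pairs += 1
    return n - pairs


def code_recessive(geno: pd.DataFrame, snp: str) -> pd.DataFrame:
    """Recode dosage for a recessive test: 2 -> 1, {0, 1} -> 0, NaN kept."""
    out = geno.copy()
    g = out[snp].to_numpy(dtype=float)
    out[snp] = np.where(np.isnan(g), np.nan, (g == 2).astype(float))
    return out


def qc_summary(ped: pd.DataFrame, geno: pd.DataFrame,
               hwe_alpha: float = 0.01) -> pd.DataFrame:
    """Per-SNP QC table: MAF, missing fraction, HWE chi2/p, Mendelian error
    count and a flag column (flagged SNPs are reported, never dropped)."""
    mend = mendelian_check(ped, geno)
    rows = []
    for snp in geno.columns:
        g = geno[snp].to_numpy(dtype=float)
        miss = float(np.isnan(g).mean())
        f = maf(geno, snp, ped)
        chi2, p = hwe_test(geno, snp, ped)
        n_mend = sum(1 for e in mend if e[2] == snp)
        rows.append({
            "snp": snp, "maf": f, "missing_frac": miss,
            "hwe_chi2": chi2, "hwe_p": p, "mendel_errors": n_mend,
            "flag_hwe": p < hwe_alpha,
        })
    return pd.DataFrame(rows).set_index("snp")
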