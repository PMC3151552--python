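"""Synthetic twin-family cohort generator.

Emulates the sampling frame of the Netherlands Twin Register survey
cohorts: MZ/DZ twin pairs with optionally both parents and up to one
brother and one sister (adult cohort), or twin pairs only (child cohort).
Genotypes follow Hardy-Weinberg founders with Mendelian transmission (MZ
co-twins share genotypes exactly); phenotypes are drawn from the factorial
association model so that the empirical moments of a generated cohort
converge to :func:`twinfactor.model.implied_cov`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FamilyDesign, Member, implied_mean, latent_correlation
from .params import (
    ADULT_AGE_MEANS,
    CHILD_AGE_OF,
    CHILD_AGES,
    ModelParams,
    occasions,
    role_occasions,
)

__all__ = [
    "FamilySpec", "CohortConfig", "TrueParams",
    "build_families", "simulate_genotypes", "simulate_phenotypes",
    "apply_missingness", "draw_phenotype_deviations",
]

#: ground-truth parameters for simulation share the ModelParams structure
TrueParams = ModelParams

TWIN_TYPES = ("MZM", "DZM", "MZF", "DZF", "DOS")

#: occasion participation probabilities emulating the published occasion
#: totals (fraction of the full sample with a score at each occasion)
DEFAULT_PARTICIPATION_ADULT = {
    "twin": {"t1991": 0.128, "t1995": 0.197, "t1997": 0.317,
             "t2000": 0.455, "t2002": 0.668},
    "sibling": {"t1997": 0.317, "t2000": 0.455, "t2002": 0.668},
    "parent": {"t2002": 0.90},
}
DEFAULT_PARTICIPATION_CHILD = {
    "twin": {"mot7": 0.887, "mot10": 0.590, "mot12": 0.396,
             "fat7": 0.652, "fat10": 0.425, "fat12": 0.297,
             "self": 0.256},
}

_ROLE_GROUP = {"twin1": "twin", "twin2": "twin", "father": "parent",
               "mother": "parent", "brother": "sibling", "sister": "sibling"}


@dataclass
class FamilySpec:
    """One family configuration: twin type, optional parents and siblings."""
    twin_type: str                # MZM / DZM / MZF / DZF / DOS
    count: int = 1
    parents: bool = False
    brothers: int = 0
    sisters: int = 0

    def __post_init__(self):
        if self.twin_type not in TWIN_TYPES:
            raise ValueError(f"unknown twin type {self.twin_type!r}")
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if not 0 <= self.brothers <= 1 or not 0 <= self.sisters <= 1:
            raise ValueError("at most one brother and one sister per family")


@dataclass
class CohortConfig:
    cohort: str = "adult"
    families: list = field(default_factory=list)   # list[FamilySpec]
    participation: dict | None = None              # role group -> {label: prob}
    maf: dict = field(default_factory=lambda: {"snp1": 0.3})
    geno_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.participation is None:
            self.participation = (DEFAULT_PARTICIPATION_ADULT
                                  if self.cohort == "adult"
                                  else DEFAULT_PARTICIPATION_CHILD)
        for grp in self.participation.values():
            for lab, pr in grp.items():
                if not 0.0 <= pr <= 1.0:
                    raise ValueError(f"participation {lab}={pr} outside [0, 1]")
        for snp, f in self.maf.items():
            if not 0.0 < f <= 0.5:
                raise ValueError(f"maf for {snp} must be in (0, 0.5]")
        if not 0.0 <= self.geno_missing_rate < 1.0:
            raise ValueError("geno_missing_rate outside [0, 1)")


# ---------------------------------------------------------------------------
# pedigree construction


def _twin_sexes(twin_type: str) -> tuple[str, str]:
    if twin_type == "DOS":
        return ("m", "f")
    s = "m" if twin_type.endswith("M") else "f"
    return (s, s)


def build_families(config: CohortConfig) -> pd.DataFrame:
    """Deterministically lay out the pedigree requested by ``config``.

    Returns a PLINK-FAM-like table with columns
    fid, iid, father, mother, sex, role, zygosity ("0" = no parent in file).
    """
    if config.cohort == "child":
        for spec in config.families:
            if spec.parents or spec.brothers or spec.sisters:
                raise ValueError(
                    "child cohort families consist of twin pairs only")
    rows = []
    fidx = 0
    for spec in config.families:
        zyg = "MZ" if spec.twin_type.startswith("MZ") else "DZ"
        s1, s2 = _twin_sexes(spec.twin_type)
        for _ in range(spec.count):
            fid = f"F{fidx:05d}"
            fidx += 1
            fa, mo = f"{fid}_FA", f"{fid}_MO"
            pat, mat = (fa, mo) if spec.parents else ("0", "0")
            if spec.parents:
                rows.append((fid, fa, "0", "0", "m", "father", "NA"))
                rows.append((fid, mo, "0", "0", "f", "mother", "NA"))
            rows.append((fid, f"{fid}_T1", pat, mat, s1, "twin1", zyg))
            rows.append((fid, f"{fid}_T2", pat, mat, s2, "twin2", zyg))
            if spec.brothers:
                rows.append((fid, f"{fid}_B1", pat, mat, "m", "brother", "NA"))
            if spec.sisters:
                rows.append((fid, f"{fid}_S1", pat, mat, "f", "sister", "NA"))
    return pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "role", "zygosity"])


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(ped: pd.DataFrame, maf, seed: int,
                       missing_rate: float = 0.0) -> pd.DataFrame:
    """Hardy-Weinberg founders, Mendelian transmission, MZ genotype sharing.

    ``maf`` is a mapping snp -> minor-allele frequency (a single float
    simulates one SNP named "snp1").  Families whose parents are absent from
    the pedigree get latent founder genotypes so DZ/sibling dosage
    correlations are still 0.5.  Returns individuals x SNPs dosage table
    (NaN = missing call).
    """
    if isinstance(maf, float):
        maf = {"snp1": maf}
    rng = np.random.default_rng(seed)
    fids = ped["fid"].to_numpy()
    fam_codes, fam_index = pd.factorize(fids)
    nfam = len(fam_index)
    out = pd.DataFrame(index=ped["iid"].to_numpy(), columns=list(maf), dtype=float)
    role = ped["role"].to_numpy()
    zyg = ped["zygosity"].to_numpy()

    n = len(ped)
    for snp, p in maf.items():
        if not 0.0 < p <= 0.5:
            raise ValueError(f"maf for {snp} must be in (0, 0.5]")
        fa_alleles = (rng.random((nfam, 2)) < p).astype(np.int8)
        mo_alleles = (rng.random((nfam, 2)) < p).astype(np.int8)
        pick_fa = rng.integers(0, 2, n)
        pick_mo = rng.integers(0, 2, n)
        dosage = (fa_alleles[fam_codes, pick_fa]
                  + mo_alleles[fam_codes, pick_mo]).astype(float)
        is_fa = role == "father"
        is_mo = role == "mother"
        dosage[is_fa] = fa_alleles.sum(axis=1)[fam_codes[is_fa]]
        dosage[is_mo] = mo_alleles.sum(axis=1)[fam_codes[is_mo]]
        # MZ co-twins share the twin1 draw exactly
        twin1_dos = np.zeros(nfam)
        t1 = role == "twin1"
        twin1_dos[fam_codes[t1]] = dosage[t1]
        mz2 = (role == "twin2") & (zyg == "MZ")
        dosage[mz2] = twin1_dos[fam_codes[mz2]]
        if missing_rate > 0:
            dosage[rng.random(n) < missing_rate] = np.nan
        out[snp] = dosage
    return out


# ---------------------------------------------------------------------------
# phenotypes


def _draw_ages(ped_grp: pd.DataFrame, cohort: str, rng) -> dict[str, dict[str, float]]:
    """Ages per iid per label for one family."""
    ages: dict[str, dict[str, float]] = {}
    if cohort == "child":
        for _, row in ped_grp.iterrows():
            a = {lab: float(CHILD_AGE_OF[lab]) for lab in occasions("child")
                 if lab != "self"}
            a["self"] = float(rng.normal(16.0, 1.3))
            ages[row.iid] = a
        return ages
    base = rng.normal(0.0, 4.0)  # family-level deviation from occasion mean age
    for _, row in ped_grp.iterrows():
        if row.role in ("twin1", "twin2"):
            off = base
        elif row.role in ("brother", "sister"):
            off = base + rng.uniform(-5.0, 5.0)
        else:
            off = base + rng.normal(28.0, 3.0)
        ages[row.iid] = {t: ADULT_AGE_MEANS[t] + off for t in occasions("adult")}
    return ages


def design_from_pedigree_rows(ped_grp: pd.DataFrame, cohort: str,
                              ages: dict | None = None,
                              dosages: dict | None = None,
                              observed: dict | None = None) -> FamilyDesign:
    """Build a :class:`FamilyDesign` from pedigree rows of one family."""
    schema = role_occasions(cohort)
    members = []
    for _, row in ped_grp.iterrows():
        obs = observed.get(row.iid) if observed is not None else None
        if obs is None:
            obs = schema[row.role]
        members.append(Member(
            iid=row.iid, role=row.role, sex=row.sex,
            zygosity=None if row.zygosity in ("NA", None) else row.zygosity,
            observed=tuple(obs),
            ages=(ages or {}).get(row.iid, {}),
            dosage=(dosages or {}).get(row.iid, math.nan),
        ))
    return FamilyDesign(fid=ped_grp["fid"].iloc[0], cohort=cohort, members=members)


def draw_phenotype_deviations(fam: FamilyDesign, p: ModelParams, n: int,
                              rng) -> np.ndarray:
    """Draw ``n`` zero-mean replicates of one family's observed entries from
    the generative structure of the model.

    Latent factors are drawn from the familial correlation matrix (unit
    variances), then loaded onto the indicators; residuals are independent
    per entry for adults, while children's residuals are built from one
    residual factor per rating age shared by the mother and father rating
    and correlated across co-twins by zygosity.  This path never touches
    :func:`~twinfactor.model.implied_cov`, so agreement of empirical and
    implied moments is a genuine cross-check.
    """
    members = fam.members
    k = len(members)
    entries = fam.entries
    d = len(entries)
    R = np.empty((k, k))
    for i, mi in enumerate(members):
        for j, mj in enumerate(members):
            R[i, j] = 1.0 if i == j else latent_correlation(mi, mj, p)
    try:
        Lr = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError as e:
        raise ValueError("latent correlation matrix not positive definite") from e
    F = rng.standard_normal((n, k)) @ Lr.T

    out = np.empty((n, d))
    if p.cohort == "adult":
        for c, (mi, lab) in enumerate(entries):
            m = members[mi]
            sd = math.sqrt(p.sigma2[m.sex][lab])
            out[:, c] = p.lam[m.sex][lab] * F[:, mi] + sd * rng.standard_normal(n)
        return out

    # child cohort: twin pairs (or a lone twin) only
    if any(m.role not in ("twin1", "twin2") for m in members):
        raise ValueError("child cohort families consist of twins only")
    zyg = members[0].zygosity or "DZ"

    def _pair_corr(rho: float) -> np.ndarray:
        """(n, k) standard normals correlated rho across co-twins."""
        if k == 1:
            return rng.standard_normal((n, 1))
        C = np.array([[1.0, rho], [rho, 1.0]])
        return rng.standard_normal((n, 2)) @ np.linalg.cholesky(C).T

    U = {a: _pair_corr(p.rho_twin[(a, zyg)]) for a in CHILD_AGES}
    V = _pair_corr(p.rho_twin[("adol", zyg)])
    for c, (mi, lab) in enumerate(entries):
        m = members[mi]
        sd = math.sqrt(p.sigma2[m.sex][lab])
        age = CHILD_AGE_OF[lab]
        if age == "adol":
            eps = sd * V[:, mi]
        else:
            rho = p.rho_raters[age]
            eps = (math.sqrt(rho) * sd * U[age][:, mi]
                   + math.sqrt(1.0 - rho) * sd * rng.standard_normal(n))
        out[:, c] = p.lam[m.sex][lab] * F[:, mi] + eps
    return out


def simulate_phenotypes(ped: pd.DataFrame, truth: ModelParams,
                        geno: pd.DataFrame | None, seed: int,
                        snp: str | None = None) -> pd.DataFrame:
    """Draw complete-data phenotypes for every individual in ``ped``.

    Returns a wide table indexed by iid with one column per occasion label
    plus ``age_<label>`` columns; entries outside a role's occasion schema
    are NaN.  ``snp`` selects the causal SNP column of ``geno`` (first
    column by default); with ``truth.beta_snp`` zero, ``geno`` may be None.
    """
    rng = np.random.default_rng(seed)
    cohort = truth.cohort
    labels = occasions(cohort)
    any_beta = truth.beta_snp["m"] != 0.0 or truth.beta_snp["f"] != 0.0
    if any_beta and geno is None:
        raise ValueError("genotypes required when beta_snp is nonzero")
    gcol = None
    if geno is not None:
        gcol = geno[snp if snp is not None else geno.columns[0]]

    cols = {lab: np.full(len(ped), np.nan) for lab in labels}
    age_cols = {f"age_{lab}": np.full(len(ped), np.nan) for lab in labels}
    iid_pos = {iid: i for i, iid in enumerate(ped["iid"])}

    for fid, grp in ped.groupby("fid", sort=False):
        ages = _draw_ages(grp, cohort, rng)
        dosages = {}
        if gcol is not None:
            dosages = {iid: float(gcol.get(iid, math.nan)) for iid in grp["iid"]}
        fam = design_from_pedigree_rows(grp, cohort, ages=ages, dosages=dosages)
        y = implied_mean(fam, truth) + draw_phenotype_deviations(fam, truth, 1, rng)[0]
        for val, (mi, lab) in zip(y, fam.entries):
            iid = fam.members[mi].iid
            cols[lab][iid_pos[iid]] = val
            age_cols[f"age_{lab}"][iid_pos[iid]] = ages[iid].get(lab, np.nan)

    out = pd.DataFrame({**cols, **age_cols}, index=ped["iid"].to_numpy())
    out.index.name = "iid"
    return out


def apply_missingness(phen: pd.DataFrame, ped: pd.DataFrame,
                      config: CohortConfig, seed: int) -> pd.DataFrame:
    """Thin phenotype entries by per-occasion, per-role participation.

    Missingness is independent across entries (missing completely at
    random); individuals losing every occasion keep their row.
    """
    rng = np.random.default_rng(seed)
    out = phen.copy()
    groups = ped.set_index("iid")["role"].map(_ROLE_GROUP)
    for grp_name, probs in config.participation.items():
        iids = groups.index[groups == grp_name]
        iids = [i for i in iids if i in out.index]
        if not iids:
            continue
        schema_labels = occasions(config.cohort)
        for lab in schema_labels:
            pr = probs.get(lab, 0.0)
            drop = rng.random(len(iids)) >= pr
            out.loc[np.asarray(iids)[drop], lab] = np.nan
    return out
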