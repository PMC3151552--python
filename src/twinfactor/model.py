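"""Implied moments of the factorial association model.

For a family with members i and indicators t the model is

    y_it = mu_t + beta_age*age_it + beta_sex*sex_i
           + lambda_{t,s(i)} * (F_i + beta_snp_{s(i)} * g_i) + eps_it

with Var(F_i) = 1 and Corr(F_i, F_j) the role/sex/zygosity-appropriate
latent correlation.  Adults have independent residuals; children's
residuals cluster through one residual factor per rating age that loads on
the mother and father rating of the same child and is correlated across
co-twins with a zygosity-specific correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import (
    CHILD_AGE_OF,
    ModelParams,
    OFFSPRING_ROLES,
    TWIN_ROLES,
    role_occasions,
)

__all__ = [
    "Member", "FamilyDesign", "latent_correlation",
    "implied_mean", "implied_cov", "snp_variance_explained", "beta_for_ve",
]


@dataclass
class Member:
    iid: str
    role: str                   # twin1/twin2/father/mother/brother/sister
    sex: str                    # "m" or "f"
    zygosity: str | None = None  # "MZ"/"DZ" for twins, None otherwise
    observed: tuple[str, ...] = ()
    ages: dict = field(default_factory=dict)   # label -> age (years)
    dosage: float = math.nan                   # minor-allele count, nan if missing


@dataclass
class FamilyDesign:
    fid: str
    cohort: str
    members: list[Member]

    @property
    def entries(self) -> list[tuple[int, str]]:
        """(member index, label) in vectorization order."""
        return [(i, t) for i, m in enumerate(self.members) for t in m.observed]

    def signature(self) -> tuple:
        """Hashable key identifying the covariance-relevant structure."""
        return (self.cohort,
                tuple((m.role, m.sex, m.zygosity, m.observed) for m in self.members))


_SEX_PAIR_DZ = {("m", "m"): "DZm", ("f", "f"): "DZf"}


def correlation_key(a: Member, b: Member) -> str:
    """Name of the latent correlation parameter linking two distinct members."""
    ra, rb = a.role, b.role
    if ra in TWIN_ROLES and rb in TWIN_ROLES:
        if a.zygosity == "MZ":
            return "MZm" if a.sex == "m" else "MZf"
        return _SEX_PAIR_DZ.get((a.sex, b.sex), "DOS")
    if ra in OFFSPRING_ROLES and rb in OFFSPRING_ROLES:
        # twin-sibling and sibling-sibling pairs share the DZ correlation
        # of the matching sex pairing
        return _SEX_PAIR_DZ.get((a.sex, b.sex), "DOS")
    if {ra, rb} == {"father", "mother"}:
        return "spousal"
    parent, child = (a, b) if ra in ("father", "mother") else (b, a)
    return ("father" if parent.role == "father" else "mother") + \
           ("_son" if child.sex == "m" else "_daughter")


def latent_correlation(a: Member, b: Member, p: ModelParams) -> float:
    """Latent A/D factor correlation between two family members."""
    if a is b:
        return 1.0
    return p.corr[correlation_key(a, b)]


def implied_mean(fam: FamilyDesign, p: ModelParams) -> np.ndarray:
    """Model-implied mean of the observed entries of ``fam``.

    The SNP term for a member with missing dosage is omitted (its phenotypes
    still contribute through mu and the covariates).  In the child cohort the
    age and sex covariates act on the adolescent self-report only.
    """
    out = []
    for m in fam.members:
        g = 0.0 if math.isnan(m.dosage) else m.dosage
        sexcode = 0.0 if m.sex == "m" else 1.0
        for t in m.observed:
            val = p.mu[t]
            covariates = p.cohort == "adult" or t == "self"
            if covariates:
                if p.beta_age != 0.0:
                    age = m.ages.get(t)
                    if age is None:
                        raise ValueError(
                            f"missing age for {m.iid}/{t} with beta_age != 0")
                    val += p.beta_age * age
                val += p.beta_sex * sexcode
            val += p.lam[m.sex][t] * (p.beta_snp[m.sex] * g)
            out.append(val)
    return np.asarray(out)


def implied_cov(fam: FamilyDesign, p: ModelParams) -> np.ndarray:
    """Model-implied covariance matrix of the observed entries of ``fam``."""
    entries = fam.entries
    members = fam.members
    k = len(members)
    R = np.empty((k, k))
    for i, mi in enumerate(members):
        for j, mj in enumerate(members):
            R[i, j] = 1.0 if i == j else latent_correlation(mi, mj, p)
    if k > 1 and np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("latent correlation matrix is not positive semi-definite")

    mem_idx = np.array([i for i, _ in entries])
    lam_col = np.array([p.lam[members[i].sex][t] for i, t in entries])
    sd_col = np.array([math.sqrt(p.sigma2[members[i].sex][t]) for i, t in entries])
    cov = np.outer(lam_col, lam_col) * R[np.ix_(mem_idx, mem_idx)]

    if p.cohort == "adult":
        cov[np.diag_indices_from(cov)] += sd_col ** 2
        return cov

    # child residual structure: one residual factor per rating age shared by
    # the mother and father rating (loading sqrt(rho_raters)*sd), correlated
    # across co-twins with a zygosity-specific correlation; the lone
    # adolescent self-report carries its whole residual as the age factor
    age_col = np.array([CHILD_AGE_OF[t] for _, t in entries])
    zyg = next((m.zygosity for m in members if m.zygosity), "DZ")
    rho_col = np.array([1.0 if a == "adol" else p.rho_raters[a] for a in age_col])
    gam_col = np.sqrt(rho_col) * sd_col
    rtw_col = np.array([p.rho_twin[(a, zyg)] for a in age_col])
    same_mem = mem_idx[:, None] == mem_idx[None, :]
    same_age = age_col[:, None] == age_col[None, :]
    # off-member entries only ever combine with the same age (mask below),
    # so row-wise rho_twin is the pair's value for that age
    weight = np.where(same_mem, 1.0, rtw_col[:, None])
    res = np.outer(gam_col, gam_col) * weight * same_age
    res[np.diag_indices_from(res)] = sd_col ** 2
    return cov + res


def snp_variance_explained(beta: float, maf: float) -> float:
    """Share of total latent-trait variance attributable to an additive SNP.

    Under Hardy-Weinberg the dosage variance is 2*maf*(1-maf); the latent
    trait is F + beta*g with Var(F) = 1, so
    VE = beta^2*2pq / (1 + beta^2*2pq).
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    v = beta * beta * 2.0 * maf * (1.0 - maf)
    return v / (1.0 + v)


def beta_for_ve(ve: float, maf: float) -> float:
    """Inverse of :func:`snp_variance_explained` (nonnegative root)."""
    if not 0 <= ve < 1:
        raise ValueError("ve must be in [0, 1)")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    return math.sqrt(ve / (1.0 - ve) / (2.0 * maf * (1.0 - maf)))
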