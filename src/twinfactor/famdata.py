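"""Raw family data arranged for fast full-information likelihood evaluation.

Families sharing the same covariance-relevant structure (member roles,
sexes, zygosities and observed-entry pattern) are collected into pattern
groups: the implied covariance is factorized once per group and the mean
structure is evaluated vectorized over the group's families.  This is what
makes simulation studies with thousands of model fits tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FamilyDesign, correlation_key
from .params import (
    CHILD_AGE_OF, CORR_KEYS, ModelParams, OFFSPRING_ROLES, RHO_AGES,
    cov_arrays, mean_arrays, occasions, role_occasions,
)

__all__ = ["PatternGroup", "build_groups", "groups_from_tables", "loglik",
           "n_families", "present_correlations"]

_LOG2PI = math.log(2.0 * math.pi)


class DesignMeta:
    """Precomputed integer indices for fast implied-moment assembly."""

    def __init__(self, fam: FamilyDesign):
        members = fam.members
        entries = fam.entries
        labels = occasions(fam.cohort)
        lab_pos = {t: j for j, t in enumerate(labels)}
        self.cohort = fam.cohort
        self.d = len(entries)
        self.mem_idx = np.array([i for i, _ in entries], dtype=int)
        self.lab_idx = np.array([lab_pos[t] for _, t in entries], dtype=int)
        self.sex_idx = np.array([0 if members[i].sex == "m" else 1
                                 for i, _ in entries], dtype=int)
        k = len(members)
        code = np.full((k, k), -1, dtype=int)
        pos = {c: j for j, c in enumerate(CORR_KEYS)}
        for i in range(k):
            for j in range(k):
                if i != j:
                    code[i, j] = pos[correlation_key(members[i], members[j])]
        self.corr_code = code[np.ix_(self.mem_idx, self.mem_idx)]
        self.diag_mask = self.corr_code < 0  # same-member entry pairs
        if fam.cohort == "child":
            age_pos = {a: j for j, a in enumerate(RHO_AGES)}
            self.age_idx = np.array(
                [age_pos[CHILD_AGE_OF[t]] for _, t in entries], dtype=int)
            zyg = next((m.zygosity for m in members if m.zygosity), "DZ")
            self.zyg_idx = 0 if zyg == "MZ" else 1
            self.same_age = self.age_idx[:, None] == self.age_idx[None, :]

    def cov(self, arrs: dict) -> np.ndarray:
        R = arrs["corr"][self.corr_code]
        R[self.diag_mask] = 1.0
        lam = arrs["lam"][self.sex_idx, self.lab_idx]
        sd2 = arrs["sig2"][self.sex_idx, self.lab_idx]
        cov = np.outer(lam, lam) * R
        if self.cohort == "adult":
            cov[np.diag_indices_from(cov)] += sd2
            return cov
        rho = arrs["rho_raters"][self.age_idx]
        gam = np.sqrt(rho * sd2)
        rtw = arrs["rho_twin"][self.age_idx, self.zyg_idx]
        weight = np.where(self.diag_mask, 1.0, rtw[:, None])
        res = np.outer(gam, gam) * weight * self.same_age
        res[np.diag_indices_from(res)] = sd2
        return cov + res


_META_CACHE: dict[tuple, DesignMeta] = {}


def design_meta(fam: FamilyDesign) -> DesignMeta:
    sig = fam.signature()
    meta = _META_CACHE.get(sig)
    if meta is None:
        meta = _META_CACHE[sig] = DesignMeta(fam)
    return meta


@dataclass
class PatternGroup:
    design: FamilyDesign          # representative family (structure only)
    y: np.ndarray                 # (n, d) observed values
    age: np.ndarray               # (n, d); zero where the age covariate is off
    sexc: np.ndarray              # (d,) sex-covariate indicator per column
    g: np.ndarray                 # (n, d) dosage broadcast per member (0 if missing)
    gb: np.ndarray                # (n, d) between-family dosage component
    gw: np.ndarray                # (n, d) within-family dosage component
    col_label: list               # occasion label per column
    col_sex: list                 # member sex per column
    fids: list

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.y.shape[1]

    def mean(self, p: ModelParams) -> np.ndarray:
        meta = design_meta(self.design)
        return self._mean(meta, mean_arrays(p), cov_arrays(p))

    def _mean(self, meta: "DesignMeta", marrs: dict, carrs: dict) -> np.ndarray:
        M = marrs["mu"][meta.lab_idx] + marrs["beta_sex"] * self.sexc
        if marrs["beta_age"] != 0.0:
            M = M + marrs["beta_age"] * self.age
        snp = marrs["bsnp"][meta.sex_idx] * self.g
        if marrs["bb"] != 0.0:
            snp = snp + marrs["bb"] * self.gb
        if marrs["bw"] != 0.0:
            snp = snp + marrs["bw"] * self.gw
        lam = carrs["lam"][meta.sex_idx, meta.lab_idx]
        return M + lam * snp


def _design_channels(fam: FamilyDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-entry dosage, between and within channels for one family.

    The between component is the family's mean dosage over genotyped
    offspring; parents enter through their own dosage in the between
    channel.  Members with missing dosage contribute zero to every channel
    (their SNP mean term is omitted).
    """
    off = [m.dosage for m in fam.members
           if m.role in OFFSPRING_ROLES and not math.isnan(m.dosage)]
    gbar = float(np.mean(off)) if off else math.nan
    g_row, gb_row, gw_row = [], [], []
    for m in fam.members:
        if math.isnan(m.dosage):
            g = gb = gw = 0.0
        elif m.role in OFFSPRING_ROLES:
            g, gb, gw = m.dosage, gbar, m.dosage - gbar
        else:
            g, gb, gw = m.dosage, m.dosage, 0.0
        for _ in m.observed:
            g_row.append(g)
            gb_row.append(gb)
            gw_row.append(gw)
    return (np.asarray(g_row), np.asarray(gb_row), np.asarray(gw_row))


def build_groups(designs: list[FamilyDesign], ys: list[np.ndarray]) -> list[PatternGroup]:
    """Group (design, data vector) pairs by covariance signature."""
    buckets: dict[tuple, list[int]] = {}
    for i, fam in enumerate(designs):
        buckets.setdefault(fam.signature(), []).append(i)
    groups = []
    for sig, idxs in buckets.items():
        rep = designs[idxs[0]]
        cohort = rep.cohort
        col_label, col_sex, sexc_row, age_on = [], [], [], []
        for m in rep.members:
            for t in m.observed:
                col_label.append(t)
                col_sex.append(m.sex)
                on = cohort == "adult" or t == "self"
                sexc_row.append((0.0 if m.sex == "m" else 1.0) if on else 0.0)
                age_on.append(on)
        d = len(col_label)
        n = len(idxs)
        y = np.empty((n, d))
        age = np.zeros((n, d))
        g = np.empty((n, d))
        gb = np.empty((n, d))
        gw = np.empty((n, d))
        fids = []
        for r, i in enumerate(idxs):
            fam = designs[i]
            y[r] = ys[i]
            c = 0
            for m in fam.members:
                for t in m.observed:
                    if age_on[c]:
                        a = m.ages.get(t)
                        age[r, c] = 0.0 if a is None else a
                    c += 1
            g[r], gb[r], gw[r] = _design_channels(fam)
            fids.append(fam.fid)
        groups.append(PatternGroup(
            design=rep, y=y, age=age, sexc=np.asarray(sexc_row),
            g=g, gb=gb, gw=gw, col_label=col_label, col_sex=col_sex,
            fids=fids))
    return groups


def groups_from_tables(ped: pd.DataFrame, phen: pd.DataFrame, cohort: str,
                       geno: pd.DataFrame | None = None, snp: str | None = None,
                       center_ages: bool = True) -> list[PatternGroup]:
    """Assemble pattern groups from pedigree / wide-phenotype / genotype tables.

    Individuals with no observed occasion are dropped (they contribute
    nothing to the likelihood); ages are centered at the mean of all
    observed age entries so that occasion intercepts refer to an
    average-aged person.
    """
    from .cohort import design_from_pedigree_rows  # cycle-free at call time

    schema = role_occasions(cohort)
    labels = occasions(cohort)
    age_cols = [f"age_{t}" for t in labels if f"age_{t}" in phen.columns]
    center = 0.0
    if center_ages and age_cols:
        vals = phen[age_cols].to_numpy(dtype=float)
        if cohort == "child":
            vals = phen[["age_self"]].to_numpy(dtype=float) \
                if "age_self" in phen.columns else vals
        obs = vals[~np.isnan(vals)]
        center = float(obs.mean()) if obs.size else 0.0

    designs, ys = [], []
    gcol = None
    if geno is not None:
        gcol = geno[snp if snp is not None else geno.columns[0]]
    for fid, grp in ped.groupby("fid", sort=False):
        observed: dict[str, tuple] = {}
        ages: dict[str, dict] = {}
        dosages: dict[str, float] = {}
        vals: dict[str, list] = {}
        for _, row in grp.iterrows():
            iid = row.iid
            if iid not in phen.index:
                continue
            obs_labels, v = [], []
            for t in schema.get(row.role, ()):
                x = phen.at[iid, t] if t in phen.columns else np.nan
                if not pd.isna(x):
                    obs_labels.append(t)
                    v.append(float(x))
            if not obs_labels:
                continue
            observed[iid] = tuple(obs_labels)
            vals[iid] = v
            a = {}
            for t in obs_labels:
                col = f"age_{t}"
                if col in phen.columns and not pd.isna(phen.at[iid, col]):
                    a[t] = float(phen.at[iid, col]) - center
            ages[iid] = a
            if gcol is not None:
                dosages[iid] = float(gcol.get(iid, math.nan))
        if not observed:
            continue
        sub = grp[grp["iid"].isin(observed)]
        fam = design_from_pedigree_rows(sub, cohort, ages=ages,
                                        dosages=dosages, observed=observed)
        designs.append(fam)
        ys.append(np.concatenate([vals[m.iid] for m in fam.members]))
    return build_groups(designs, ys)


def n_families(groups: list[PatternGroup]) -> int:
    return sum(grp.n for grp in groups)


def present_correlations(groups: list[PatternGroup]) -> list[str]:
    """Latent correlation parameters identified by the family structures."""
    from .model import correlation_key

    seen = set()
    for grp in groups:
        ms = grp.design.members
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                seen.add(correlation_key(ms[i], ms[j]))
    order = ["MZm", "MZf", "DZm", "DZf", "DOS", "father_son",
             "father_daughter", "mother_son", "mother_daughter", "spousal"]
    return [f"corr:{k}" for k in order if k in seen]


class Bundle:
    """Pattern groups stacked by dimension for batched likelihood evaluation.

    Within a bucket of equal observed dimension the implied covariances of
    all patterns are assembled, inverted and log-det'ed with one batched
    numpy call each, and every family row is handled in a single einsum.
    ``reuse_cov=True`` (valid while no covariance parameter moves) caches
    the inverses after the first evaluation.
    """

    def __init__(self, groups: list[PatternGroup]):
        self.groups = groups
        self.buckets = []
        by_key: dict[tuple, list[int]] = {}
        for gi, grp in enumerate(groups):
            by_key.setdefault((grp.d, grp.design.cohort), []).append(gi)
        for (d, cohort), idxs in by_key.items():
            metas = [design_meta(groups[i].design) for i in idxs]
            m = len(idxs)
            b = {
                "d": d, "cohort": cohort, "m": m,
                "counts": np.array([groups[i].n for i in idxs]),
                "corr_code": np.stack([mt.corr_code for mt in metas]),
                "diag": np.stack([mt.corr_code < 0 for mt in metas]),
                "sex_idx": np.stack([mt.sex_idx for mt in metas]),
                "lab_idx": np.stack([mt.lab_idx for mt in metas]),
                "cache": None,
            }
            if cohort == "child":
                b["age_idx"] = np.stack([mt.age_idx for mt in metas])
                b["zyg_idx"] = np.array([mt.zyg_idx for mt in metas])
                b["same_age"] = np.stack([mt.same_age for mt in metas])
            gidx = np.repeat(np.arange(m), b["counts"])
            b["gidx"] = gidx
            b["Y"] = np.vstack([groups[i].y for i in idxs])
            b["age"] = np.vstack([groups[i].age for i in idxs])
            b["sexc"] = np.vstack([np.broadcast_to(groups[i].sexc,
                                                   groups[i].y.shape)
                                   for i in idxs])
            b["g"] = np.vstack([groups[i].g for i in idxs])
            b["gb"] = np.vstack([groups[i].gb for i in idxs])
            b["gw"] = np.vstack([groups[i].gw for i in idxs])
            b["lab_rows"] = b["lab_idx"][gidx]
            b["sex_rows"] = b["sex_idx"][gidx]
            self.buckets.append(b)

    def _cov_stack(self, b: dict, carrs: dict) -> np.ndarray | None:
        lam = carrs["lam"][b["sex_idx"], b["lab_idx"]]       # (m, d)
        sd2 = carrs["sig2"][b["sex_idx"], b["lab_idx"]]
        R = carrs["corr"][b["corr_code"]]
        R[b["diag"]] = 1.0
        cov = lam[:, :, None] * lam[:, None, :] * R
        ar = np.arange(b["d"])
        if b["cohort"] == "adult":
            cov[:, ar, ar] += sd2
        else:
            rho = carrs["rho_raters"][b["age_idx"]]
            gam = np.sqrt(rho * sd2)
            rtw = carrs["rho_twin"][b["age_idx"], b["zyg_idx"][:, None]]
            weight = np.where(b["diag"], 1.0, rtw[:, :, None])
            res = gam[:, :, None] * gam[:, None, :] * weight * b["same_age"]
            res[:, ar, ar] = sd2
            cov = cov + res
        return cov if np.all(np.isfinite(cov)) else None

    def loglik(self, p: ModelParams, reuse_cov: bool = False) -> float:
        carrs = cov_arrays(p)
        marrs = mean_arrays(p)
        total = 0.0
        for b in self.buckets:
            if reuse_cov and b["cache"] is not None:
                inv, logdet = b["cache"]
            else:
                cov = self._cov_stack(b, carrs)
                if cov is None:
                    return -math.inf
                sign, logdet = np.linalg.slogdet(cov)
                if np.any(sign <= 0):
                    return -math.inf
                try:
                    inv = np.linalg.inv(cov)
                except np.linalg.LinAlgError:
                    return -math.inf
                if reuse_cov:
                    b["cache"] = (inv, logdet)
            lam_rows = carrs["lam"][b["sex_rows"], b["lab_rows"]]
            M = (marrs["mu"][b["lab_rows"]] + marrs["beta_sex"] * b["sexc"]
                 + marrs["beta_age"] * b["age"])
            snp = marrs["bsnp"][b["sex_rows"]] * b["g"]
            if marrs["bb"] != 0.0:
                snp = snp + marrs["bb"] * b["gb"]
            if marrs["bw"] != 0.0:
                snp = snp + marrs["bw"] * b["gw"]
            resid = b["Y"] - M - lam_rows * snp
            quad = float(np.einsum("nd,nde,ne->", resid, inv[b["gidx"]], resid))
            total += -0.5 * (float(b["counts"] @ (b["d"] * _LOG2PI + logdet))
                             + quad)
        return total

    def clear_cov_cache(self) -> None:
        for b in self.buckets:
            b["cache"] = None


def loglik(groups: list[PatternGroup], p: ModelParams) -> float:
    """FIML log-likelihood: sum over families of the multivariate-normal
    log density of each family's observed entries under the implied moments.

    Returns ``-inf`` when the implied covariance of any pattern is not
    positive definite, so optimizers reject the step.
    """
    return Bundle(groups).loglik(p)
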