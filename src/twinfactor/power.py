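"""Power analysis for the latent-factor association design, and the
correlation-based heritability estimate.

The noncentrality-parameter (NCP) route follows the Satorra-Saris
procedure: the SNP effect implied by a target variance-explained (VE) is
written into the model's implied moments — one moment group per family
configuration x genotype configuration, weighted by Hardy-Weinberg and
Mendelian transmission probabilities — and the no-effect model (free
occasion intercepts and familial correlations, frozen measurement
structure) is fitted to those moments by minimizing the ML discrepancy.
The minimized, count-weighted discrepancy is the NCP of the
likelihood-ratio test, and power follows from the noncentral chi-square
distribution.  A Monte-Carlo route (simulate, fit, count rejections)
cross-validates the NCP route.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .famdata import PatternGroup
from .fiml import fit, lrt
from .model import FamilyDesign, beta_for_ve, implied_cov, implied_mean
from .params import ModelParams, from_internal, to_internal

__all__ = [
    "PowerDesign", "PowerResult", "ncp_power", "min_detectable_ve",
    "univariate_design", "univariate_power", "monte_carlo_power",
    "falconer_h2", "family_genotype_dist",
]


@dataclass
class PowerDesign:
    """A roster of family configurations with counts, plus test settings."""
    families: list                      # list[(FamilyDesign, count)]
    params: ModelParams                 # no-SNP model (beta_snp ignored)
    maf: float = 0.5
    alpha: float = 0.01
    df: int = 1
    target_power: float = 0.8
    test_sex: str | None = None         # None: every sex present in the roster
    free_correlations: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")

    def n_unique_genotypes(self) -> float:
        total = 0.0
        for fam, count in self.families:
            mz = sum(1 for m in fam.members if m.zygosity == "MZ")
            total += count * (len(fam.members) - mz // 2)
        return total


@dataclass
class PowerResult:
    power: float
    ncp: float
    ve: float
    method: str = "ncp"
    min_ve: float | None = None


# ---------------------------------------------------------------------------
# genotype distributions


def _hw(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


_TRANSMIT = {0: (1.0, 0.0), 1: (0.5, 0.5), 2: (0.0, 1.0)}


def _child_dist(gf: int, gm: int) -> dict[int, float]:
    out: dict[int, float] = {}
    for af, pf in enumerate(_TRANSMIT[gf]):
        for am, pm in enumerate(_TRANSMIT[gm]):
            if pf * pm > 0:
                out[af + am] = out.get(af + am, 0.0) + pf * pm
    return out


def family_genotype_dist(fam: FamilyDesign, maf: float
                         ) -> list[tuple[float, tuple]]:
    """Joint dosage distribution over a family's members under
    Hardy-Weinberg founders and Mendelian transmission.

    MZ co-twins share one draw; other offspring are conditionally
    independent given (possibly latent) parental genotypes, which gives the
    dosage correlation of 0.5 between DZ twins and siblings.
    """
    hw = _hw(maf)
    members = fam.members
    # offspring slots: MZ twins collapse to one slot
    slot_of: list = [None] * len(members)
    slots = []
    mz_slot = None
    for i, m in enumerate(members):
        if m.role in ("father", "mother"):
            continue
        if m.zygosity == "MZ":
            if mz_slot is None:
                mz_slot = len(slots)
                slots.append("mz")
            slot_of[i] = mz_slot
        else:
            slot_of[i] = len(slots)
            slots.append("ind")
    acc: dict[tuple, float] = {}
    for gf in range(3):
        for gm in range(3):
            w_par = hw[gf] * hw[gm]
            child = _child_dist(gf, gm)
            items = list(child.items())
            for combo in itertools.product(items, repeat=len(slots)):
                w = w_par
                for (_, pw) in combo:
                    w *= pw
                if w == 0.0:
                    continue
                dos = []
                for i, m in enumerate(members):
                    if m.role == "father":
                        dos.append(float(gf))
                    elif m.role == "mother":
                        dos.append(float(gm))
                    else:
                        dos.append(float(combo[slot_of[i]][0]))
                key = tuple(dos)
                acc[key] = acc.get(key, 0.0) + w
    return [(w, dos) for dos, w in acc.items()]


# ---------------------------------------------------------------------------
# NCP machinery


def _pattern_structures(design: PowerDesign, beta: float):
    """Per unique family pattern: count, implied alt moments and genotype
    mean shifts, plus the mu-design matrix."""
    p = design.params.copy()
    p.beta_snp = {"m": 0.0, "f": 0.0}
    buckets: dict[tuple, list] = {}
    for fam, count in design.families:
        sig = fam.signature()
        if sig in buckets:
            buckets[sig][1] += count
        else:
            buckets[sig] = [fam, count]
    mu_labels = sorted({t for fam, _ in design.families
                        for m in fam.members for t in m.observed})
    mu_idx = {t: j for j, t in enumerate(mu_labels)}

    structures = []
    for fam, count in buckets.values():
        Sa = implied_cov(fam, p)
        base = implied_mean(fam, p)
        cols = [(i, t) for i, m in enumerate(fam.members) for t in m.observed]
        d = len(cols)
        X = np.zeros((d, len(mu_labels)))
        for r, (i, t) in enumerate(cols):
            X[r, mu_idx[t]] = 1.0
        lam_col = np.array([p.lam[fam.members[i].sex][t] for i, t in cols])
        configs = family_genotype_dist(fam, design.maf)
        W = np.array([w for w, _ in configs])
        shifts = np.array([[beta * lam_col[r] * dos[i]
                            for r, (i, _) in enumerate(cols)]
                           for _, dos in configs])
        from .famdata import design_meta

        structures.append({
            "fam": fam, "count": count, "Sa": Sa,
            "logdetSa": float(np.linalg.slogdet(Sa)[1]),
            "base": base, "X": X, "W": W, "shifts": shifts,
            "meta": design_meta(fam),
        })
    return structures, mu_labels


def _discrepancy(structures, null_params: ModelParams, n_mu: int) -> float:
    """Count-weighted ML discrepancy of the null model against the
    alternative moments, with occasion intercepts profiled out by GLS."""
    from .params import cov_arrays

    carrs = cov_arrays(null_params)
    A = np.zeros((n_mu, n_mu))
    b = np.zeros(n_mu)
    C = 0.0
    covsum = 0.0
    for s in structures:
        try:
            S0 = s["meta"].cov(carrs)
            cf = cho_factor(S0, lower=True)
        except (np.linalg.LinAlgError, ValueError):
            return math.inf
        d = S0.shape[0]
        logdet0 = 2.0 * float(np.log(np.diag(cf[0])).sum())
        tr = float(np.trace(cho_solve(cf, s["Sa"])))
        covsum += s["count"] * (logdet0 - s["logdetSa"] + tr - d)
        SX = cho_solve(cf, s["X"])
        A += s["count"] * (s["X"].T @ SX)
        means = s["base"] + s["shifts"]          # (configs, d)
        Sm = cho_solve(cf, means.T)              # (d, configs)
        C += s["count"] * float(s["W"] @ np.einsum("cd,dc->c", means, Sm))
        abar = s["W"] @ means
        b += s["count"] * (SX.T @ abar)
    try:
        mu_hat = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return math.inf
    return covsum + C - float(b @ mu_hat)


def _ncp(design: PowerDesign, ve: float) -> float:
    if ve == 0.0:
        return 0.0
    beta = beta_for_ve(ve, design.maf)
    structures, mu_labels = _pattern_structures(design, beta)
    null = design.params.copy()
    null.beta_snp = {"m": 0.0, "f": 0.0}

    corr_names: list[str] = []
    if design.free_correlations:
        from .model import correlation_key

        seen = set()
        for s in structures:
            ms = s["fam"].members
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    seen.add(correlation_key(ms[i], ms[j]))
        corr_names = [f"corr:{k}" for k in sorted(seen)]
    if not corr_names:
        return _discrepancy(structures, null, len(mu_labels))

    work = null.copy()

    def objective(x):
        for name, xv in zip(corr_names, x):
            work.set(name, from_internal(float(xv), "atanh"))
        return _discrepancy(structures, work, len(mu_labels))

    x0 = np.array([to_internal(null.get(n), "atanh") for n in corr_names])
    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            options={"ftol": 1e-12, "gtol": 1e-8})
    return float(min(res.fun, objective(x0)))


def power_from_ncp(ncp: float, df: int, alpha: float) -> float:
    crit = stats.chi2.ppf(1.0 - alpha, df)
    return float(stats.ncx2.sf(crit, df, ncp)) if ncp > 0 else alpha


def ncp_power(design: PowerDesign, ve: float) -> PowerResult:
    """Power of the likelihood-ratio SNP test at a given proportion of
    latent-trait variance explained."""
    if not 0.0 <= ve < 1.0:
        raise ValueError("ve must be in [0, 1)")
    ncp = _ncp(design, ve)
    return PowerResult(power=power_from_ncp(ncp, design.df, design.alpha),
                       ncp=ncp, ve=ve, method="ncp")


def min_detectable_ve(design: PowerDesign, lo: float = 1e-5, hi: float = 0.4
                      ) -> float:
    """Smallest variance-explained reaching the design's target power,
    found by bisection on the NCP-based power curve.  Returned as a
    percentage."""
    target = design.target_power

    def f(ve):
        return ncp_power(design, ve).power - target

    if f(hi) < 0:
        raise ValueError("target power not reachable below ve=%.2f" % hi)
    ve = optimize.brentq(f, lo, hi, xtol=1e-7, rtol=1e-10)
    return 100.0 * ve


# ---------------------------------------------------------------------------
# univariate comparison design


def univariate_design(design: PowerDesign, label: str | None = None
                      ) -> PowerDesign:
    """The single-measurement version of a design: every member keeps one
    occasion (default: last adult survey / age-7 maternal rating), with the
    same loading, residual and familial-correlation structure."""
    if label is None:
        label = "t2002" if design.params.cohort == "adult" else "mot7"
    fams = []
    for fam, count in design.families:
        members = [type(m)(iid=m.iid, role=m.role, sex=m.sex,
                           zygosity=m.zygosity, observed=(label,),
                           ages=dict(m.ages), dosage=m.dosage)
                   for m in fam.members]
        fams.append((FamilyDesign(fid=fam.fid, cohort=fam.cohort,
                                  members=members), count))
    return PowerDesign(families=fams, params=design.params, maf=design.maf,
                       alpha=design.alpha, df=design.df,
                       target_power=design.target_power,
                       test_sex=design.test_sex,
                       free_correlations=design.free_correlations)


def univariate_power(design: PowerDesign, ve: float,
                     label: str | None = None) -> PowerResult:
    return ncp_power(univariate_design(design, label), ve)


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation


def _beta_names(design: PowerDesign) -> list[str]:
    sexes = sorted({m.sex for fam, _ in design.families for m in fam.members})
    if design.test_sex is not None:
        return [f"beta_snp:{design.test_sex}"]
    return [f"beta_snp:{s}" for s in sexes]


def monte_carlo_power(design: PowerDesign, ve: float, n_reps: int, seed: int,
                      ) -> PowerResult:
    """Empirical rejection rate of the LRT over simulated replicates.

    Covariance parameters are held at their design values in both the null
    and alternative fits (the mean-structure test this validates is the
    same one the NCP route evaluates with ``free_correlations=False``).
    At ``ve=0`` the result estimates the test's type-I error rate.
    """
    rng = np.random.default_rng(seed)
    beta = beta_for_ve(ve, design.maf) if ve > 0 else 0.0
    structures, mu_labels = _pattern_structures(design, beta if beta else 1.0)
    p0 = design.params.copy()
    p0.beta_snp = {"m": 0.0, "f": 0.0}
    beta_names = _beta_names(design)
    free_mu = [f"mu:{t}" for t in mu_labels]
    df = len(beta_names)

    pre = []
    for s in structures:
        fam = s["fam"]
        cols = [(i, t) for i, m in enumerate(fam.members) for t in m.observed]
        col_label = [t for _, t in cols]
        col_sex = [fam.members[i].sex for i, _ in cols]
        L = np.linalg.cholesky(s["Sa"])
        configs = family_genotype_dist(fam, design.maf)
        g_rows = np.array([[dos[i] for i, _ in cols] for _, dos in configs])
        shifts = (beta * np.array([p0.lam[sx][t] for sx, t
                                   in zip(col_sex, col_label)]) * g_rows)
        pre.append((fam, int(round(s["count"])), L, s["base"], s["W"],
                    g_rows, shifts, col_label, col_sex))

    rejections = 0
    for _ in range(n_reps):
        groups = []
        for fam, n, L, base, W, g_rows, shifts, col_label, col_sex in pre:
            idx = rng.choice(len(W), size=n, p=W / W.sum())
            z = rng.standard_normal((n, L.shape[0]))
            y = base + shifts[idx] + z @ L.T
            d = L.shape[0]
            groups.append(PatternGroup(
                design=fam, y=y, age=np.zeros((n, d)), sexc=np.zeros(d),
                g=g_rows[idx], gb=np.zeros((n, d)), gw=np.zeros((n, d)),
                col_label=col_label, col_sex=col_sex, fids=[""] * n))
        alt = fit(groups, p0, free_mu + beta_names, compute_se=False)
        nul = fit(groups, p0, free_mu, compute_se=False)
        _, _, pval = lrt(alt, nul)
        if pval < design.alpha:
            rejections += 1
    rate = rejections / n_reps
    ncp_ref = _ncp(PowerDesign(families=design.families, params=design.params,
                               maf=design.maf, alpha=design.alpha, df=df,
                               test_sex=design.test_sex,
                               free_correlations=False), ve)
    return PowerResult(power=rate, ncp=ncp_ref, ve=ve, method="monte-carlo")


# ---------------------------------------------------------------------------
# heritability from latent-factor twin correlations


def falconer_h2(r_mz_list, r_dz_list) -> tuple[float, float, float]:
    """Rough ACE decomposition of the latent factor from pooled MZ and DZ
    twin correlations: a2 = 2(rMZ - rDZ), c2 = 2rDZ - rMZ, e2 = 1 - rMZ.
    When the implied shared-environment share is negative the AE fallback
    sets c2 = 0 and a2 = rMZ.
    """
    r_mz = [float(r) for r in np.atleast_1d(r_mz_list)]
    r_dz = [float(r) for r in np.atleast_1d(r_dz_list)]
    for r in (*r_mz, *r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    rmz = float(np.mean(r_mz))
    rdz = float(np.mean(r_dz))
    a2 = 2.0 * (rmz - rdz)
    c2 = 2.0 * rdz - rmz
    e2 = 1.0 - rmz
    if c2 < 0.0:
        a2, c2 = rmz, 0.0
    return a2, c2, e2
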