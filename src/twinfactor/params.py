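"""Model parameters for the longitudinal latent-factor association model.

Two cohort schemas are supported:

* ``adult`` — a single anxious-depression (A/D) score per survey occasion
  (1991, 1995, 1997, 2000, 2002).  Twins may participate at all five
  occasions, parents only at the last, siblings at the last three.
* ``child`` — seven indicators per twin: mother and father CBCL ratings at
  ages 7, 10 and 12 plus one adolescent self-report.

A single latent A/D factor with unit variance loads on every indicator with
sex-specific loadings.  Familial resemblance is expressed through
correlations between relatives' latent factors; in the child model the
residuals additionally cluster within twin pairs through one residual factor
per rating age.  A SNP enters the model as a fixed mean effect on the latent
factor (sex-specific additive dosage coefficient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# occasion / indicator schemas

ADULT_OCCASIONS: tuple[str, ...] = ("t1991", "t1995", "t1997", "t2000", "t2002")
ADULT_ROLE_OCCASIONS: dict[str, tuple[str, ...]] = {
    "twin1": ADULT_OCCASIONS,
    "twin2": ADULT_OCCASIONS,
    "father": ("t2002",),
    "mother": ("t2002",),
    "brother": ("t1997", "t2000", "t2002"),
    "sister": ("t1997", "t2000", "t2002"),
}

CHILD_INDICATORS: tuple[str, ...] = (
    "mot7", "fat7", "mot10", "fat10", "mot12", "fat12", "self",
)
#: rating age of each child indicator ("adol" = adolescent self-report)
CHILD_AGE_OF: dict[str, str] = {
    "mot7": "7", "fat7": "7", "mot10": "10", "fat10": "10",
    "mot12": "12", "fat12": "12", "self": "adol",
}
CHILD_AGES: tuple[str, ...] = ("7", "10", "12")
CHILD_ROLE_OCCASIONS: dict[str, tuple[str, ...]] = {
    "twin1": CHILD_INDICATORS,
    "twin2": CHILD_INDICATORS,
}

SEXES = ("m", "f")

#: latent-factor correlation parameters between relatives
CORR_KEYS = (
    "MZm", "MZf", "DZm", "DZf", "DOS",
    "father_son", "father_daughter", "mother_son", "mother_daughter",
    "spousal",
)

OFFSPRING_ROLES = frozenset({"twin1", "twin2", "brother", "sister"})
TWIN_ROLES = frozenset({"twin1", "twin2"})


def occasions(cohort: str) -> tuple[str, ...]:
    if cohort == "adult":
        return ADULT_OCCASIONS
    if cohort == "child":
        return CHILD_INDICATORS
    raise ValueError(f"unknown cohort {cohort!r}")


def role_occasions(cohort: str) -> dict[str, tuple[str, ...]]:
    return ADULT_ROLE_OCCASIONS if cohort == "adult" else CHILD_ROLE_OCCASIONS


# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """All parameters of the factorial association model.

    Parameters are addressed by flat string names (``"lam:f:t2000"``,
    ``"corr:MZf"``, ``"beta_snp:m"``, ...) so that estimation code can
    designate arbitrary free/fixed subsets.  The latent factor variance is
    identically 1 and is not a parameter.
    """

    cohort: str = "adult"
    mu: dict = field(default_factory=dict)            # label -> intercept
    beta_age: float = 0.0
    beta_sex: float = 0.0
    lam: dict = field(default_factory=dict)           # sex -> {label: loading}
    sigma2: dict = field(default_factory=dict)        # sex -> {label: residual var}
    corr: dict = field(default_factory=dict)          # CORR_KEYS -> correlation
    # child residual structure (empty for adults)
    rho_raters: dict = field(default_factory=dict)    # age -> mother/father residual corr
    rho_twin: dict = field(default_factory=dict)      # (age, zygosity) -> residual-factor corr
    beta_snp: dict = field(default_factory=lambda: {"m": 0.0, "f": 0.0})
    beta_between: float = 0.0
    beta_within: float = 0.0

    # -- flat-name access -------------------------------------------------

    def get(self, name: str) -> float:
        kind, *rest = name.split(":")
        if kind == "mu":
            return self.mu[rest[0]]
        if kind == "lam":
            return self.lam[rest[0]][rest[1]]
        if kind == "sigma2":
            return self.sigma2[rest[0]][rest[1]]
        if kind == "corr":
            return self.corr[rest[0]]
        if kind == "rho_raters":
            return self.rho_raters[rest[0]]
        if kind == "rho_twin":
            return self.rho_twin[(rest[0], rest[1])]
        if kind == "beta_snp":
            return self.beta_snp[rest[0]]
        if kind in ("beta_age", "beta_sex", "beta_between", "beta_within"):
            return getattr(self, kind)
        raise KeyError(name)

    def set(self, name: str, value: float) -> None:
        kind, *rest = name.split(":")
        if kind == "mu":
            self.mu[rest[0]] = value
        elif kind == "lam":
            self.lam[rest[0]][rest[1]] = value
        elif kind == "sigma2":
            self.sigma2[rest[0]][rest[1]] = value
        elif kind == "corr":
            self.corr[rest[0]] = value
        elif kind == "rho_raters":
            self.rho_raters[rest[0]] = value
        elif kind == "rho_twin":
            self.rho_twin[(rest[0], rest[1])] = value
        elif kind == "beta_snp":
            self.beta_snp[rest[0]] = value
        elif kind in ("beta_age", "beta_sex", "beta_between", "beta_within"):
            setattr(self, kind, value)
        else:
            raise KeyError(name)

    def copy(self) -> "ModelParams":
        return ModelParams(
            cohort=self.cohort,
            mu=dict(self.mu),
            beta_age=self.beta_age,
            beta_sex=self.beta_sex,
            lam={s: dict(v) for s, v in self.lam.items()},
            sigma2={s: dict(v) for s, v in self.sigma2.items()},
            corr=dict(self.corr),
            rho_raters=dict(self.rho_raters),
            rho_twin=dict(self.rho_twin),
            beta_snp=dict(self.beta_snp),
            beta_between=self.beta_between,
            beta_within=self.beta_within,
        )

    # -- name groups ------------------------------------------------------

    def names_mu(self) -> list[str]:
        return [f"mu:{t}" for t in occasions(self.cohort)]

    def names_measurement(self) -> list[str]:
        """Loadings, residual variances and (child) residual structure."""
        labels = occasions(self.cohort)
        names = [f"lam:{s}:{t}" for s in SEXES for t in labels]
        names += [f"sigma2:{s}:{t}" for s in SEXES for t in labels]
        if self.cohort == "child":
            names += [f"rho_raters:{a}" for a in CHILD_AGES]
            names += [f"rho_twin:{a}:{z}" for a in (*CHILD_AGES, "adol")
                      for z in ("MZ", "DZ")]
        return names

    def names_correlations(self) -> list[str]:
        if self.cohort == "child":
            return [f"corr:{k}" for k in ("MZm", "MZf", "DZm", "DZf", "DOS")]
        return [f"corr:{k}" for k in CORR_KEYS]

    def names_covariates(self) -> list[str]:
        return ["beta_age", "beta_sex"]

    def all_names(self) -> list[str]:
        return (self.names_mu() + self.names_covariates()
                + self.names_measurement() + self.names_correlations()
                + ["beta_snp:m", "beta_snp:f", "beta_between", "beta_within"])

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for k, v in self.corr.items():
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"correlation corr:{k}={v} outside [-1, 1]")
        for (a, z), v in self.rho_twin.items():
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"rho_twin:{a}:{z}={v} outside [-1, 1]")
        for a, v in self.rho_raters.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rho_raters:{a}={v} outside [0, 1]")
        for s in self.sigma2:
            for t, v in self.sigma2[s].items():
                if v < 0:
                    raise ValueError(f"sigma2:{s}:{t}={v} negative")

    # -- serialization ----------------------------------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"cohort = {self.cohort}\n")
            for name in self.all_names():
                fh.write(f"{name} = {self.get(name)!r}\n")

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        entries: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                entries[key.strip()] = val.strip()
        cohort = entries.pop("cohort")
        p = empty_params(cohort)
        for name, val in entries.items():
            p.set(name, float(val))
        return p


RHO_AGES = ("7", "10", "12", "adol")


def cov_arrays(p: "ModelParams") -> dict:
    """Covariance-relevant parameters as plain arrays (fast-path layout:
    sex axis 0 = m/f, label axis in cohort occasion order)."""
    labels = occasions(p.cohort)
    lam = np.array([[p.lam[s][t] for t in labels] for s in SEXES])
    sig2 = np.array([[p.sigma2[s][t] for t in labels] for s in SEXES])
    corr = np.array([p.corr.get(k, 0.0) for k in CORR_KEYS])
    if p.cohort == "child":
        rho_raters = np.array([p.rho_raters[a] for a in CHILD_AGES] + [1.0])
        rho_twin = np.array([[p.rho_twin[(a, z)] for z in ("MZ", "DZ")]
                             for a in RHO_AGES])
    else:
        rho_raters = np.ones(4)
        rho_twin = np.zeros((4, 2))
    return {"lam": lam, "sig2": sig2, "corr": corr,
            "rho_raters": rho_raters, "rho_twin": rho_twin}


def mean_arrays(p: "ModelParams") -> dict:
    labels = occasions(p.cohort)
    return {"mu": np.array([p.mu[t] for t in labels]),
            "beta_age": p.beta_age, "beta_sex": p.beta_sex,
            "bsnp": np.array([p.beta_snp["m"], p.beta_snp["f"]]),
            "bb": p.beta_between, "bw": p.beta_within}


#: parameters that enter the implied covariance matrix (anything else is
#: mean-structure only, which lets the FIML engine cache factorizations)
def covariance_param_prefixes() -> tuple[str, ...]:
    return ("lam:", "sigma2:", "corr:", "rho_raters:", "rho_twin:")


def is_covariance_param(name: str) -> bool:
    return name.startswith(covariance_param_prefixes())


def transform_kind(name: str) -> str:
    """Internal optimization scale: variances on log, correlations on atanh,
    rater-residual shares on logit, everything else unconstrained."""
    if name.startswith("sigma2:"):
        return "log"
    if name.startswith(("corr:", "rho_twin:")):
        return "atanh"
    if name.startswith("rho_raters:"):
        return "logit"
    return "identity"


def to_internal(value: float, kind: str) -> float:
    if kind == "log":
        return math.log(max(value, 1e-12))
    if kind == "atanh":
        return math.atanh(min(max(value, -1 + 1e-10), 1 - 1e-10))
    if kind == "logit":
        v = min(max(value, 1e-10), 1 - 1e-10)
        return math.log(v / (1 - v))
    return value


def from_internal(value: float, kind: str) -> float:
    if kind == "log":
        return math.exp(value)
    if kind == "atanh":
        return math.tanh(value)
    if kind == "logit":
        return 1.0 / (1.0 + math.exp(-value))
    return value


# ---------------------------------------------------------------------------
# reference parameter sets


def empty_params(cohort: str) -> ModelParams:
    labels = occasions(cohort)
    p = ModelParams(
        cohort=cohort,
        mu={t: 0.0 for t in labels},
        lam={s: {t: 0.0 for t in labels} for s in SEXES},
        sigma2={s: {t: 1.0 for t in labels} for s in SEXES},
        corr={k: 0.0 for k in CORR_KEYS},
    )
    if cohort == "child":
        p.rho_raters = {a: 0.0 for a in CHILD_AGES}
        p.rho_twin = {(a, z): 0.0 for a in (*CHILD_AGES, "adol") for z in ("MZ", "DZ")}
    return p


# Proportion of each measure's variance attributed to the latent A/D factor
# in the published Netherlands Twin Register analyses; loadings are the
# square roots (total variance of each normalized measure is ~1).
_ADULT_VE = {
    "m": (0.43, 0.55, 0.62, 0.65, 0.62),
    "f": (0.45, 0.59, 0.64, 0.73, 0.62),
}
_CHILD_VE = {  # mot7, fat7, mot10, fat10, mot12, fat12, self
    "m": (0.51, 0.46, 0.61, 0.56, 0.55, 0.53, 0.06),
    "f": (0.52, 0.46, 0.57, 0.51, 0.55, 0.50, 0.09),
}
_ADULT_CORR = {
    "MZm": 0.69, "MZf": 0.70, "DZm": 0.31, "DZf": 0.30, "DOS": 0.29,
    # parent-offspring and spousal latent correlations are not published;
    # defaults chosen as plausible values for a trait ~70% heritable
    "father_son": 0.25, "father_daughter": 0.25,
    "mother_son": 0.25, "mother_daughter": 0.25,
    "spousal": 0.0,
}
_CHILD_CORR = {
    "MZm": 0.77, "MZf": 0.74, "DZm": 0.40, "DZf": 0.43, "DOS": 0.48,
    "father_son": 0.0, "father_daughter": 0.0,
    "mother_son": 0.0, "mother_daughter": 0.0, "spousal": 0.0,
}
# residual-factor twin correlations (unpublished): parental ratings of both
# co-twins come from the same informant, so residual clustering is strong
# and only mildly zygosity dependent; the self-report shares no rater.
_CHILD_RHO_TWIN = {
    ("7", "MZ"): 0.75, ("7", "DZ"): 0.55,
    ("10", "MZ"): 0.75, ("10", "DZ"): 0.55,
    ("12", "MZ"): 0.75, ("12", "DZ"): 0.55,
    ("adol", "MZ"): 0.30, ("adol", "DZ"): 0.15,
}
_CHILD_RHO_RATERS = {"7": 0.18, "10": 0.06, "12": 0.17}

#: mean (SD) of age at each adult survey occasion in the full sample
ADULT_AGE_MEANS = {
    "t1991": 19.9, "t1995": 21.5, "t1997": 27.4, "t2000": 30.2, "t2002": 39.8,
}
ADULT_AGE_SD = {
    "t1991": 1.2, "t1995": 2.2, "t1997": 9.4, "t2000": 9.8, "t2002": 13.5,
}


def default_params(cohort: str) -> ModelParams:
    """Reference parameter set with published loadings and twin correlations."""
    p = empty_params(cohort)
    ve = _ADULT_VE if cohort == "adult" else _CHILD_VE
    labels = occasions(cohort)
    for s in SEXES:
        for t, v in zip(labels, ve[s]):
            p.lam[s][t] = math.sqrt(v)
            p.sigma2[s][t] = 1.0 - v
    p.corr = dict(_ADULT_CORR if cohort == "adult" else _CHILD_CORR)
    if cohort == "child":
        p.rho_twin = dict(_CHILD_RHO_TWIN)
        p.rho_raters = dict(_CHILD_RHO_RATERS)
    return p
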