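"""Full-information maximum-likelihood estimation and likelihood-ratio tests.

Estimation maximizes the raw-data multivariate-normal likelihood over a
caller-designated free subset of :class:`~twinfactor.params.ModelParams`.
Internally variances are optimized on the log scale and correlations on the
atanh scale so the search is unconstrained; results are reported on the
natural scale.  When every free parameter enters only the mean structure,
the per-pattern covariance factorizations are computed once and reused —
the common case in the two-stage association protocol, where measurement
parameters are frozen at their total-sample estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from . import famdata
from .famdata import Bundle, PatternGroup, present_correlations
from .params import (
    ModelParams, from_internal, is_covariance_param, to_internal, transform_kind,
)

__all__ = ["FitResult", "fit", "lrt", "stage1_fit", "stage2_fit",
           "two_stage_protocol", "moment_start"]


@dataclass
class FitResult:
    params: ModelParams
    minus2ll: float
    free: list                    # flattened free parameter names
    n_free: int                   # free parameter count (tied cluster = 1)
    converged: bool
    se: dict = field(default_factory=dict)
    boundary: bool = False
    n_families: int = 0
    message: str = ""


def _clusters(free, tied) -> list[list[str]]:
    tied = [list(c) for c in tied]
    in_tied = {n for c in tied for n in c}
    clusters = [[n] for n in free if n not in in_tied]
    clusters.extend(c for c in tied if c)
    return clusters


def fit(groups: list[PatternGroup], init: ModelParams, free: list[str],
        tied: tuple = (), compute_se: bool = True, maxiter: int = 1000
        ) -> FitResult:
    """Quasi-Newton FIML fit of the parameters named in ``free``.

    ``tied`` lists clusters of parameter names constrained equal (each
    cluster counts as one free parameter).  Deterministic given data and
    ``init``.  Non-convergence is reported in the result, not raised.
    """
    clusters = _clusters(free, tied)
    if not clusters:
        raise ValueError("at least one free parameter is required")
    kinds = []
    for c in clusters:
        ks = {transform_kind(n) for n in c}
        if len(ks) != 1:
            raise ValueError(f"tied cluster {c} mixes optimization scales")
        kinds.append(ks.pop())

    all_free = [n for c in clusters for n in c]
    mean_only = not any(is_covariance_param(n) for n in all_free)
    bundle = Bundle(groups)

    work = init.copy()

    def unpack(x) -> ModelParams:
        for c, kind, xv in zip(clusters, kinds, x):
            v = from_internal(float(xv), kind)
            for n in c:
                work.set(n, v)
        return work

    def objective(x) -> float:
        ll = bundle.loglik(unpack(x), reuse_cov=mean_only)
        return 1e10 if not math.isfinite(ll) else -ll

    x0 = np.array([to_internal(init.get(c[0]), k)
                   for c, k in zip(clusters, kinds)])
    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 200000,
                                     "ftol": 1e-9, "gtol": 1e-5})
    est = unpack(res.x).copy()
    boundary = bool(np.any(np.abs(res.x[[k != "identity" for k in kinds]]) > 8.0)) \
        if any(k != "identity" for k in kinds) else False

    se: dict[str, float] = {}
    if compute_se:
        se = _standard_errors(bundle, est, clusters, mean_only)

    return FitResult(
        params=est, minus2ll=2.0 * float(res.fun), free=all_free,
        n_free=len(clusters), converged=bool(res.success), se=se,
        boundary=boundary, n_families=famdata.n_families(groups),
        message=str(res.message))


def _standard_errors(bundle: Bundle, est: ModelParams, clusters,
                     mean_only: bool) -> dict:
    """Observed-information standard errors on the natural scale."""
    work = est.copy()

    def negll_nat(v) -> float:
        for c, vv in zip(clusters, v):
            for n in c:
                work.set(n, float(vv))
        ll = bundle.loglik(work, reuse_cov=mean_only)
        return 1e10 if not math.isfinite(ll) else -ll

    v0 = np.array([est.get(c[0]) for c in clusters])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess1(v0, negll_nat)
            cov = np.linalg.inv(H)
        diag = np.diag(cov)
        ses = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        ses = np.full(len(clusters), np.nan)
    out = {}
    for c, s in zip(clusters, ses):
        for n in c:
            out[n] = float(s)
    return out


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested restriction.

    Returns (statistic, df, p).  A materially negative statistic signals a
    failed fit of the full model and raises; tiny negatives from optimizer
    tolerance are clipped to zero.
    """
    if not set(reduced.free) <= set(full.free):
        raise ValueError("reduced model's free set must nest within the full model's")
    stat = reduced.minus2ll - full.minus2ll
    if stat < -1e-4:
        raise ValueError(
            f"negative LRT statistic {stat:.3g}: refit with better start values")
    stat = max(stat, 0.0)
    df = full.n_free - reduced.n_free
    if df == 0:
        return stat, 0, 1.0  # identical free sets: degenerate test
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# two-stage association protocol


def moment_start(groups: list[PatternGroup], cohort: str) -> ModelParams:
    """Crude moment-based starting values for a stage-1 fit."""
    from .params import default_params

    p = default_params(cohort)
    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    for grp in groups:
        for j, lab in enumerate(grp.col_label):
            sums[lab] = sums.get(lab, 0.0) + float(grp.y[:, j].sum())
            ns[lab] = ns.get(lab, 0) + grp.n
    for lab, s in sums.items():
        p.mu[lab] = s / max(ns[lab], 1)
    for k in p.corr:
        p.corr[k] = min(max(p.corr[k], 0.05), 0.9)
    return p


def stage1_free(p: ModelParams, include_age: bool = True,
                include_sex: bool = True) -> list[str]:
    names = p.names_mu() + p.names_measurement() + p.names_correlations()
    if include_age:
        names.append("beta_age")
    if include_sex:
        names.append("beta_sex")
    return names


def stage1_fit(groups: list[PatternGroup], init: ModelParams | None = None,
               cohort: str = "adult", free: list[str] | None = None,
               compute_se: bool = False) -> FitResult:
    """Measurement-model fit on the total sample (no genotypes)."""
    if init is None:
        init = moment_start(groups, cohort)
    if free is None:
        has_age = any(np.any(grp.age != 0.0) for grp in groups)
        free = stage1_free(init, include_age=has_age)
    # only correlations identified by the present family structures
    present = set(present_correlations(groups))
    free = [n for n in free if not n.startswith("corr:") or n in present]
    return fit(groups, init, free, compute_se=compute_se)


def stage2_fit(geno_groups: list[PatternGroup], stage1_params: ModelParams,
               free_betas: tuple = ("beta_snp:m", "beta_snp:f"),
               tied: tuple = (), free_correlations: bool = True,
               compute_se: bool = True) -> FitResult:
    """Genotyped-subsample fit with measurement parameters frozen.

    Factor loadings and the residual structure stay at their stage-1
    estimates; the familial latent correlations are re-estimated because
    they absorb SNP-induced covariance, and the per-sex SNP effects are
    estimated (or fixed at zero by leaving them out of ``free_betas``).
    """
    init = stage1_params.copy()
    init.beta_snp = {"m": 0.0, "f": 0.0}
    init.beta_between = 0.0
    init.beta_within = 0.0
    free = list(free_betas)
    if free_correlations:
        free = present_correlations(geno_groups) + free
    free += init.names_mu()  # intercepts re-estimated in the subsample
    return fit(geno_groups, init, free, tied=tied, compute_se=compute_se)


def two_stage_protocol(total_groups: list[PatternGroup],
                       geno_groups: list[PatternGroup],
                       cohort: str = "adult",
                       init: ModelParams | None = None
                       ) -> tuple[FitResult, FitResult]:
    """Stage-1 measurement fit on the total sample, then the stage-2
    SNP-effect fit on the genotyped subsample with loadings and residual
    terms constrained at the stage-1 estimates."""
    s1 = stage1_fit(total_groups, init=init, cohort=cohort)
    s2 = stage2_fit(geno_groups, s1.params)
    return s1, s2
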