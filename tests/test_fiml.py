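"""FIML engine: likelihood oracle identities, estimation, LRT and the
two-stage protocol."""

import numpy as np
import pytest
from scipy import stats

import twinfactor as tf
from twinfactor.cohort import simulate_phenotypes
from twinfactor.famdata import build_groups, groups_from_tables, loglik
from twinfactor.fiml import fit, lrt, stage1_fit, stage2_fit, two_stage_protocol
from twinfactor.model import FamilyDesign, Member, implied_cov, implied_mean

from conftest import adult_pair, make_adult_cohort


def _family_with_data(seed=0, occ=("t1991", "t1997", "t2002")):
    fam = FamilyDesign("f", "adult", [
        Member("a", "twin1", "m", "DZ", occ, dosage=1.0),
        Member("b", "twin2", "f", "DZ", occ[:2], dosage=2.0),
        Member("c", "mother", "f", None, ("t2002",), dosage=0.0)])
    p = tf.default_params("adult")
    p.beta_snp = {"m": 0.2, "f": 0.1}
    rng = np.random.default_rng(seed)
    y = rng.normal(size=len(fam.entries))
    return fam, y, p


class TestLoglikOracle:
    def test_equals_direct_mvn_density(self):
        # independent oracle: scipy's multivariate normal with the full
        # implied moments on complete data
        fam, y, p = _family_with_data()
        groups = build_groups([fam], [y])
        expect = stats.multivariate_normal.logpdf(
            y, mean=implied_mean(fam, p), cov=implied_cov(fam, p))
        assert loglik(groups, p) == pytest.approx(expect, abs=1e-8)

    def test_single_member_single_occasion(self):
        p = tf.default_params("adult")
        fam = FamilyDesign("f", "adult", [
            Member("a", "twin1", "f", "DZ", ("t2000",))])
        y = np.array([0.7])
        var = p.lam["f"]["t2000"] ** 2 + p.sigma2["f"]["t2000"]
        mean = p.mu["t2000"] + p.beta_sex * 1.0
        expect = stats.norm.logpdf(0.7, loc=mean, scale=np.sqrt(var))
        assert loglik(build_groups([fam], [y]), p) == pytest.approx(expect,
                                                                    abs=1e-10)

    def test_marginalization_identity(self):
        # dropping an observation equals dropping its row/column from the
        # implied moments (MVN marginalization)
        fam, y, p = _family_with_data()
        reduced = FamilyDesign("f", "adult", [
            Member("a", "twin1", "m", "DZ", ("t1991", "t2002"), dosage=1.0),
            Member("b", "twin2", "f", "DZ", ("t1991", "t1997"), dosage=2.0),
            Member("c", "mother", "f", None, ("t2002",), dosage=0.0)])
        y_red = np.delete(y, 1)  # drop twin1's t1997 entry
        expect = stats.multivariate_normal.logpdf(
            y_red, mean=implied_mean(reduced, p), cov=implied_cov(reduced, p))
        assert loglik(build_groups([reduced], [y_red]), p) == \
            pytest.approx(expect, abs=1e-8)

    def test_invariant_to_family_and_member_order(self):
        p = tf.default_params("adult")
        p.beta_snp = {"m": 0.2, "f": 0.1}
        rng = np.random.default_rng(3)
        fams, ys = [], []
        for k, zyg in enumerate(["MZ", "DZ", "MZ"]):
            fam = adult_pair(zyg, "m", occ=("t1995", "t2000"),
                             dosages=(1.0, 1.0))
            fams.append(fam)
            ys.append(rng.normal(size=4))
        ll = loglik(build_groups(fams, ys), p)
        ll_rev = loglik(build_groups(fams[::-1], ys[::-1]), p)
        assert ll == pytest.approx(ll_rev, abs=1e-10)
        # swap members within each family (and their data blocks)
        fams_sw = []
        for fam in fams:
            a, b = fam.members
            fams_sw.append(FamilyDesign(fam.fid, "adult", [b, a]))
        ys_sw = [np.concatenate([y[2:], y[:2]]) for y in ys]
        assert loglik(build_groups(fams_sw, ys_sw), p) == \
            pytest.approx(ll, abs=1e-10)

    def test_non_psd_returns_minus_inf(self):
        fam, y, p = _family_with_data()
        bad = p.copy()
        for t in bad.sigma2["m"]:
            bad.sigma2["m"][t] = 0.0
            bad.sigma2["f"][t] = 0.0
        bad.corr = {k: 0.0 for k in bad.corr}
        # loadings make the factor part singular with zero residuals
        assert loglik(build_groups([fam], [y]), bad) == -np.inf


class TestFit:
    def test_mu_recovers_weighted_mean(self):
        # closed-form oracle: with only mu free and unit-independent model,
        # the MLE of mu is the GLS (here: plain) mean of the observations
        p = tf.empty_params("adult")
        for s in ("m", "f"):
            for t in p.lam[s]:
                p.sigma2[s][t] = 1.0
        rng = np.random.default_rng(1)
        fams, ys = [], []
        for k in range(300):
            fams.append(FamilyDesign(str(k), "adult", [
                Member("a", "twin1", "m", "DZ", ("t1991",))]))
            ys.append(rng.normal(0.7, 1.0, 1))
        groups = build_groups(fams, ys)
        res = fit(groups, p, ["mu:t1991"])
        sample_mean = float(np.concatenate(ys).mean())
        assert res.params.mu["t1991"] == pytest.approx(sample_mean, abs=1e-4)
        assert res.converged

    def test_nested_model_never_fits_better(self, adult_truth):
        cfg, ped, phen, geno, truth = make_adult_cohort(
            n_per_type=30, seed=10, beta=(0.1, 0.2))
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        full = stage2_fit(groups, truth, compute_se=False)
        red = stage2_fit(groups, truth, free_betas=(), compute_se=False)
        assert full.minus2ll <= red.minus2ll + 1e-6

    def test_beta_recovery_within_3se(self):
        # measurement parameters fixed at truth, only the SNP effects free
        cfg, ped, phen, geno, truth = make_adult_cohort(
            n_per_type=160, seed=20, beta=(0.0, 0.25))
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        res = fit(groups, truth, ["beta_snp:m", "beta_snp:f"])
        assert abs(res.params.beta_snp["f"] - 0.25) < 3 * res.se["beta_snp:f"]
        assert abs(res.params.beta_snp["m"] - 0.0) < 3 * res.se["beta_snp:m"]

    def test_no_free_parameters_raises(self):
        fam, y, p = _family_with_data()
        with pytest.raises(ValueError, match="free parameter"):
            fit(build_groups([fam], [y]), p, [])


class TestLrt:
    def test_identical_fits_give_zero(self):
        cfg, ped, phen, geno, truth = make_adult_cohort(n_per_type=20, seed=30)
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        r = fit(groups, truth, ["beta_snp:m"], compute_se=False)
        stat, df, p = lrt(r, r)
        assert stat == 0.0
        assert p == 1.0

    def test_df_counting(self):
        cfg, ped, phen, geno, truth = make_adult_cohort(n_per_type=20, seed=30)
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        full = stage2_fit(groups, truth, compute_se=False)
        red_m = stage2_fit(groups, truth, free_betas=("beta_snp:f",),
                           compute_se=False)
        red_0 = stage2_fit(groups, truth, free_betas=(), compute_se=False)
        assert lrt(full, red_0)[1] == 2   # joint beta_m = beta_f = 0
        assert lrt(full, red_m)[1] == 1   # per-sex test
        assert lrt(red_m, red_0)[1] == 1

    def test_non_nested_rejected(self):
        cfg, ped, phen, geno, truth = make_adult_cohort(n_per_type=20, seed=30)
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        a = fit(groups, truth, ["beta_snp:m"], compute_se=False)
        b = fit(groups, truth, ["beta_snp:f"], compute_se=False)
        with pytest.raises(ValueError, match="nest"):
            lrt(a, b)


class TestTwoStage:
    def test_protocol(self):
        cfg, ped, phen, geno, truth = make_adult_cohort(
            n_per_type=110, seed=40, beta=(0.0, 0.25), maf=0.4)
        total = groups_from_tables(ped, phen, "adult")
        genod = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        s1, s2 = two_stage_protocol(total, genod, cohort="adult")
        # stage-2 measurement parameters equal stage-1 values exactly
        for name in s1.params.names_measurement():
            assert s2.params.get(name) == s1.params.get(name)
        # recovers the sex-specific effects within 3 SE
        assert abs(s2.params.beta_snp["f"] - 0.25) < 3 * s2.se["beta_snp:f"]
        assert abs(s2.params.beta_snp["m"]) < 3 * s2.se["beta_snp:m"]

    def test_null_subsample_correlations_match_stage1(self):
        # genotyped sample = total sample and beta truth 0: stage-2
        # re-estimated correlations stay near the stage-1 values
        cfg, ped, phen, geno, truth = make_adult_cohort(
            n_per_type=110, seed=41, beta=(0.0, 0.0))
        total = groups_from_tables(ped, phen, "adult")
        genod = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        s1, s2 = two_stage_protocol(total, genod, cohort="adult")
        for key in ("MZm", "MZf", "DZm", "DZf", "DOS"):
            assert s2.params.corr[key] == pytest.approx(s1.params.corr[key],
                                                        abs=0.02)
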