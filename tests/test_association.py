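"""Association tests: sex-specific SNP effects, dosage orientation,
between/within stratification decomposition and recessive re-coding."""

import numpy as np
import pandas as pd
import pytest

import twinfactor as tf
from twinfactor.association import (assoc_table, between_within_test,
                                    recessive_test, test_snp)
from twinfactor.cohort import (CohortConfig, FamilySpec, build_families,
                               simulate_genotypes, simulate_phenotypes)
from twinfactor.famdata import groups_from_tables

from conftest import make_adult_cohort


@pytest.fixture(scope="module")
def effect_cohort():
    return make_adult_cohort(n_per_type=120, seed=50, beta=(0.0, 0.3),
                             maf=0.4)


class TestSnpTest:
    def test_detects_female_effect(self, effect_cohort):
        cfg, ped, phen, geno, truth = effect_cohort
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        res = test_snp(groups, truth, "snp1")
        assert res.p_f < 0.01
        assert res.p_m > 0.01
        assert abs(res.beta_f - 0.3) < 3 * res.se_f

    def test_orientation_flip_negates_beta(self):
        # within one sex the free intercepts absorb the 2*beta*lambda shift,
        # so re-orienting the dosage flips the estimate exactly
        truth = tf.default_params("adult")
        truth.beta_snp = {"m": 0.3, "f": 0.0}
        cfg = CohortConfig(families=[FamilySpec("MZM", 100),
                                     FamilySpec("DZM", 100)],
                           maf={"snp1": 0.4}, seed=55)
        ped = build_families(cfg)
        geno = simulate_genotypes(ped, cfg.maf, seed=56)
        phen = simulate_phenotypes(ped, truth, geno, seed=57)
        flipped = geno.copy()
        flipped["snp1"] = 2.0 - flipped["snp1"]
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        groups_f = groups_from_tables(ped, phen, "adult", geno=flipped,
                                      snp="snp1")
        r1 = test_snp(groups, truth, "snp1", free_correlations=False)
        r2 = test_snp(groups_f, truth, "snp1", free_correlations=False)
        assert r2.beta_m == pytest.approx(-r1.beta_m, abs=1e-3)
        assert np.log10(r2.p_m) == pytest.approx(np.log10(r1.p_m), abs=0.05)

    def test_wald_close_to_lrt(self, effect_cohort):
        cfg, ped, phen, geno, truth = effect_cohort
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        r_lrt = test_snp(groups, truth, "snp1", free_correlations=False)
        r_wald = test_snp(groups, truth, "snp1", wald=True,
                          free_correlations=False)
        assert np.log10(r_wald.p_f) == pytest.approx(np.log10(r_lrt.p_f),
                                                     abs=0.8)

    def test_monomorphic_raises(self, effect_cohort):
        cfg, ped, phen, geno, truth = effect_cohort
        mono = geno.copy()
        mono["snp1"] = 0.0
        groups = groups_from_tables(ped, phen, "adult", geno=mono, snp="snp1")
        with pytest.raises(ValueError, match="monomorphic"):
            test_snp(groups, truth, "snp1")


def _two_subpopulation_tables(n_fam=400, seed=60):
    """Stratification construction: two subpopulations differing in both
    allele frequency and trait mean, no true SNP effect."""
    truth = tf.default_params("adult")
    peds, phens, genos = [], [], []
    for k, (freq, shift) in enumerate([(0.1, -0.4), (0.5, 0.4)]):
        cfg = CohortConfig(families=[FamilySpec("DZM", n_fam // 2)],
                           maf={"s": freq}, seed=seed + k)
        ped = build_families(cfg)
        ped["fid"] = f"P{k}_" + ped["fid"]
        ped["iid"] = f"P{k}_" + ped["iid"]
        ped[["father", "mother"]] = "0"
        geno = simulate_genotypes(ped, cfg.maf, seed=seed + 10 + k)
        phen = simulate_phenotypes(ped, truth, geno, seed=seed + 20 + k)
        phen[list(tf.params.ADULT_OCCASIONS)] += shift
        peds.append(ped), phens.append(phen), genos.append(geno)
    return (pd.concat(peds, ignore_index=True), pd.concat(phens),
            pd.concat(genos), truth)


class TestBetweenWithin:
    def test_stratification_inflates_between_only(self):
        ped, phen, geno, truth = _two_subpopulation_tables()
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="s")
        bb, bw, p_eq = between_within_test(groups, truth, "s",
                                           free_correlations=False)
        assert abs(bb) > 2 * abs(bw)
        assert abs(bb) > 0.15
        assert abs(bw) < 0.15

    def test_homogeneous_between_equals_within(self):
        cfg, ped, phen, geno, truth = make_adult_cohort(
            n_per_type=150, seed=70, beta=(0.25, 0.25), maf=0.4)
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
        bb, bw, p_eq = between_within_test(groups, truth, "snp1",
                                           free_correlations=False)
        assert bb == pytest.approx(bw, abs=0.25)
        assert p_eq > 0.01

    def test_mz_only_design_undefined(self):
        cfg = CohortConfig(families=[FamilySpec("MZM", 40)], maf={"s": 0.3})
        ped = build_families(cfg)
        geno = simulate_genotypes(ped, cfg.maf, seed=1)
        truth = tf.default_params("adult")
        phen = simulate_phenotypes(ped, truth, geno, seed=2)
        groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="s")
        with pytest.raises(ValueError, match="within-family"):
            between_within_test(groups, truth, "s")


class TestRecessive:
    def _recessive_cohort(self, seed=80, n=150):
        # purely recessive truth: only minor-allele homozygotes shift
        truth = tf.default_params("adult")
        cfg = CohortConfig(families=[
            FamilySpec("MZM", n), FamilySpec("DZM", n)], maf={"s": 0.5},
            seed=seed)
        ped = build_families(cfg)
        geno = simulate_genotypes(ped, cfg.maf, seed=seed + 1)
        rec_truth = truth.copy()
        rec_truth.beta_snp = {"m": 0.45, "f": 0.0}
        rec_geno = tf.code_recessive(geno, "s")
        phen = simulate_phenotypes(ped, rec_truth, rec_geno, seed=seed + 2)
        return ped, phen, geno, truth

    def test_recessive_beats_additive_on_recessive_truth(self):
        ped, phen, geno, truth = self._recessive_cohort()
        groups_add = groups_from_tables(ped, phen, "adult", geno=geno, snp="s")
        r_add = test_snp(groups_add, truth, "s", free_correlations=False)
        r_rec = recessive_test((ped, phen, geno), truth, "s",
                               free_correlations=False)
        assert r_rec.model == "recessive"
        assert r_rec.p_m < r_add.p_m

    def test_no_homozygotes_reported_na(self):
        ped, phen, geno, truth = self._recessive_cohort()
        geno2 = geno.copy()
        geno2.loc[geno2["s"] == 2.0, "s"] = 1.0
        res = recessive_test((ped, phen, geno2), truth, "s")
        assert np.isnan(res.p_m)
        assert "homozygote" in res.note


def test_result_table_round_trip(tmp_path, effect_cohort):
    from twinfactor import io

    cfg, ped, phen, geno, truth = effect_cohort
    groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="snp1")
    res = test_snp(groups, truth, "snp1", free_correlations=False)
    table = assoc_table([res])
    path = tmp_path / "assoc.tsv"
    io.write_table(table, path)
    back = io.read_table(path)
    for col in ("beta_m", "beta_f", "p_m", "p_f", "p_joint"):
        assert back.at["snp1", col] == pytest.approx(table.at["snp1", col])
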