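"""Genotype QC: allele frequency, Hardy-Weinberg, Mendelian errors and
unique-genotype accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinfactor as tf
from twinfactor.cohort import CohortConfig, FamilySpec, build_families, \
    simulate_genotypes
from twinfactor.qc import (code_recessive, hwe_exact_test, hwe_test, maf,
                           mendelian_check, qc_summary, unique_genotype_count)


def geno_from_counts(n_aa, n_ab, n_bb):
    dosages = [0.0] * n_aa + [1.0] * n_ab + [2.0] * n_bb
    idx = [f"i{k}" for k in range(len(dosages))]
    return pd.DataFrame({"s": dosages}, index=idx)


def trio_tables(gf, gm, gc):
    ped = pd.DataFrame({
        "fid": ["F"] * 3, "iid": ["fa", "mo", "kid"],
        "father": ["0", "0", "fa"], "mother": ["0", "0", "mo"],
        "sex": ["m", "f", "m"], "role": ["father", "mother", "twin1"],
        "zygosity": ["NA", "NA", "DZ"]})
    geno = pd.DataFrame({"s": [gf, gm, gc]}, index=["fa", "mo", "kid"])
    return ped, geno


class TestMaf:
    def test_balanced(self):
        assert maf(geno_from_counts(25, 50, 25), "s") == 0.5

    def test_skewed(self):
        assert maf(geno_from_counts(81, 18, 1), "s") == pytest.approx(0.1)

    def test_orientation_always_minor(self):
        # counting the major allele still reports the minor frequency
        assert maf(geno_from_counts(1, 18, 81), "s") == pytest.approx(0.1)

    def test_simulated_frequency(self):
        cfg = CohortConfig(families=[FamilySpec("DZM", 5000, parents=True)],
                           maf={"s": 0.3})
        ped = build_families(cfg)
        geno = simulate_genotypes(ped, cfg.maf, seed=1)
        founders = ped[ped["role"].isin(["father", "mother"])]
        f = maf(geno.loc[founders["iid"]], "s")
        assert abs(f - 0.3) < 3 * np.sqrt(0.3 * 0.7 / (2 * len(founders)))

    def test_all_missing_raises(self):
        geno = pd.DataFrame({"s": [np.nan, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            maf(geno, "s")

    def test_mz_pair_counted_once(self):
        ped = pd.DataFrame({
            "fid": ["F", "F"], "iid": ["t1", "t2"],
            "father": ["0", "0"], "mother": ["0", "0"],
            "sex": ["m", "m"], "role": ["twin1", "twin2"],
            "zygosity": ["MZ", "MZ"]})
        geno = pd.DataFrame({"s": [2.0, 2.0]}, index=["t1", "t2"])
        geno = pd.concat([geno, pd.DataFrame({"s": [0.0, 0.0]},
                                             index=["u1", "u2"])])
        ped = pd.concat([ped, pd.DataFrame({
            "fid": ["G", "H"], "iid": ["u1", "u2"], "father": ["0", "0"],
            "mother": ["0", "0"], "sex": ["m", "m"],
            "role": ["twin1", "twin1"], "zygosity": ["DZ", "DZ"]})],
            ignore_index=True)
        # dedup: one of {2,2} plus {0,0} -> minor freq 2/6
        assert maf(geno, "s", ped=ped) == pytest.approx(1 / 3)


class TestHwe:
    def test_perfect_hwe(self):
        chi2, p = hwe_test(geno_from_counts(25, 50, 25), "s")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_all_heterozygote(self):
        chi2, _ = hwe_test(geno_from_counts(0, 100, 0), "s")
        assert chi2 == pytest.approx(100.0)

    def test_hand_computed_chi2(self):
        # brute-force oracle: q=0.5, expected 25/50/25
        obs = np.array([30, 40, 30])
        expect = np.array([25, 50, 25])
        oracle = float(((obs - expect) ** 2 / expect).sum())
        chi2, p = hwe_test(geno_from_counts(30, 40, 30), "s")
        assert chi2 == pytest.approx(oracle) == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_monomorphic_convention(self):
        chi2, p = hwe_test(geno_from_counts(50, 0, 0), "s")
        assert (chi2, p) == (0.0, 1.0)

    def test_null_rejection_rate_matches_size(self):
        # many null SNPs on founders: rejection rate ~ alpha
        n_snps = 300
        cfg = CohortConfig(families=[FamilySpec("DZM", 400, parents=True)],
                           maf={f"s{k}": 0.3 for k in range(n_snps)})
        ped = build_families(cfg)
        geno = simulate_genotypes(ped, cfg.maf, seed=7)
        founders = ped[ped["role"].isin(["father", "mother"])]["iid"]
        rej = np.mean([hwe_test(geno.loc[founders], s)[1] < 0.05
                       for s in geno.columns])
        assert abs(rej - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_snps)

    def test_exact_test_reasonable(self):
        p_exact = hwe_exact_test(geno_from_counts(30, 40, 30), "s")
        _, p_chi2 = hwe_test(geno_from_counts(30, 40, 30), "s")
        assert 0.0 < p_exact < 0.2
        assert abs(p_exact - p_chi2) < 0.05


class TestMendel:
    def test_impossible_child_flagged(self):
        ped, geno = trio_tables(0, 0, 1)
        assert mendelian_check(ped, geno) == [("F", "kid", "s")]

    def test_obligate_het_ok(self):
        ped, geno = trio_tables(0, 2, 1)
        assert mendelian_check(ped, geno) == []

    def test_mz_discordance_flagged(self):
        ped = pd.DataFrame({
            "fid": ["F", "F"], "iid": ["t1", "t2"],
            "father": ["0", "0"], "mother": ["0", "0"],
            "sex": ["f", "f"], "role": ["twin1", "twin2"],
            "zygosity": ["MZ", "MZ"]})
        geno = pd.DataFrame({"s": [0.0, 1.0]}, index=["t1", "t2"])
        assert mendelian_check(ped, geno) == [("F", "t2", "s")]


class TestUniqueGenotypes:
    @pytest.mark.parametrize("n_ind,n_mz_pairs,expected", [
        (562, 42, 520),    # genotyped adult males
        (552, 160, 392),   # genotyped girls
        (100, 0, 100),     # no MZ pairs: plain count
    ])
    def test_accounting(self, n_ind, n_mz_pairs, expected):
        rows, geno_idx = [], []
        for k in range(n_mz_pairs):
            for t in (1, 2):
                rows.append((f"MZ{k}", f"MZ{k}_t{t}", "0", "0", "m",
                             f"twin{t}", "MZ"))
                geno_idx.append(f"MZ{k}_t{t}")
        for k in range(n_ind - 2 * n_mz_pairs):
            rows.append((f"S{k}", f"S{k}_i", "0", "0", "m", "twin1", "DZ"))
            geno_idx.append(f"S{k}_i")
        ped = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother",
                                          "sex", "role", "zygosity"])
        geno = pd.DataFrame({"s": np.zeros(len(geno_idx))}, index=geno_idx)
        assert unique_genotype_count(ped, geno, "m") == expected

    def test_incomplete_mz_pair_not_deduplicated(self):
        ped = pd.DataFrame([
            ("F", "t1", "0", "0", "f", "twin1", "MZ"),
            ("F", "t2", "0", "0", "f", "twin2", "MZ")],
            columns=["fid", "iid", "father", "mother", "sex", "role",
                     "zygosity"])
        geno = pd.DataFrame({"s": [1.0]}, index=["t1"])
        assert unique_genotype_count(ped, geno, "f") == 1


class TestRecessive:
    def test_recoding(self):
        geno = pd.DataFrame({"s": [0.0, 1.0, 2.0, np.nan]},
                            index=list("abcd"))
        out = code_recessive(geno, "s")
        assert list(out["s"][:3]) == [0.0, 0.0, 1.0]
        assert np.isnan(out["s"]["d"])


def test_qc_summary_flags_not_drops():
    cfg = CohortConfig(families=[FamilySpec("MZM", 50), FamilySpec("DZF", 50)],
                       maf={"a": 0.3, "b": 0.4}, geno_missing_rate=0.05)
    ped = build_families(cfg)
    geno = simulate_genotypes(ped, cfg.maf, seed=2,
                              missing_rate=cfg.geno_missing_rate)
    rep = qc_summary(ped, geno)
    assert list(rep.index) == ["a", "b"]          # flagged SNPs stay listed
    assert rep["mendel_errors"].eq(0).all()
    assert rep["missing_frac"].between(0, 0.15).all()
    assert rep["maf"].between(0, 0.5).all()
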