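import numpy as np
import pytest

import twinfactor as tf
from twinfactor.cohort import (CohortConfig, FamilySpec, build_families,
                               simulate_genotypes, simulate_phenotypes)
from twinfactor.model import FamilyDesign, Member
from twinfactor.params import ADULT_OCCASIONS, CHILD_INDICATORS


@pytest.fixture(scope="session")
def adult_truth():
    p = tf.default_params("adult")
    p.beta_age = 0.01
    p.beta_sex = 0.3
    return p


@pytest.fixture(scope="session")
def child_truth():
    return tf.default_params("child")


def make_adult_cohort(n_per_type=50, parents=False, seed=0, truth=None,
                      maf=0.3, beta=(0.0, 0.0)):
    """Complete-data adult cohort with all five twin-pair types."""
    cfg = CohortConfig(cohort="adult", families=[
        FamilySpec("MZM", n_per_type), FamilySpec("DZM", n_per_type),
        FamilySpec("MZF", n_per_type), FamilySpec("DZF", n_per_type),
        FamilySpec("DOS", n_per_type, parents=parents)],
        maf={"snp1": maf}, seed=seed)
    ped = build_families(cfg)
    geno = simulate_genotypes(ped, cfg.maf, seed=seed + 1)
    if truth is None:
        truth = tf.default_params("adult")
    truth = truth.copy()
    truth.beta_snp = {"m": beta[0], "f": beta[1]}
    phen = simulate_phenotypes(ped, truth, geno, seed=seed + 2)
    return cfg, ped, phen, geno, truth


def adult_pair(zyg="MZ", sex="m", occ=ADULT_OCCASIONS, dosages=(np.nan, np.nan)):
    z = zyg if zyg in ("MZ", "DZ") else None
    return FamilyDesign("fam", "adult", [
        Member("a", "twin1", sex, z, tuple(occ), dosage=dosages[0]),
        Member("b", "twin2", sex, z, tuple(occ), dosage=dosages[1])])


def child_pair(zyg="MZ", sex="m", occ=CHILD_INDICATORS):
    return FamilyDesign("fam", "child", [
        Member("a", "twin1", sex, zyg, tuple(occ)),
        Member("b", "twin2", sex, zyg, tuple(occ))])
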