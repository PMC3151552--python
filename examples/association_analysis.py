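"""Two-stage latent-factor association analysis on a simulated cohort.

Simulates a female-specific SNP effect (beta_f = 0.3 on the latent factor,
~4% of latent-trait variance at MAF 0.4), runs the stage-1 measurement fit
on the total sample, then the stage-2 per-SNP tests in the genotyped
subsample, including the between/within-family stratification check.
"""

import twinfactor as tf
from twinfactor.cohort import CohortConfig, FamilySpec
from twinfactor.famdata import groups_from_tables
from twinfactor.fiml import stage1_fit

cfg = CohortConfig(
    cohort="adult",
    families=[FamilySpec(t, 80) for t in ("MZM", "DZM", "MZF", "DZF", "DOS")],
    maf={"rsX": 0.4}, seed=7)
ped = tf.build_families(cfg)
geno = tf.simulate_genotypes(ped, cfg.maf, seed=8)
truth = tf.default_params("adult")
truth.beta_snp = {"m": 0.0, "f": 0.3}
phen = tf.simulate_phenotypes(ped, truth, geno, seed=9)

total = groups_from_tables(ped, phen, "adult")
s1 = stage1_fit(total, cohort="adult")
print(f"stage 1 converged: {s1.converged}  "
      f"rMZf={s1.params.corr['MZf']:.2f} rDZf={s1.params.corr['DZf']:.2f}")

geno_groups = groups_from_tables(ped, phen, "adult", geno=geno, snp="rsX")
res = tf.test_snp(geno_groups, s1.params, "rsX")
print(f"\nadditive test: beta_m={res.beta_m:+.3f} (p={res.p_m:.3f})  "
      f"beta_f={res.beta_f:+.3f} (p={res.p_f:.2g})  joint p={res.p_joint:.2g}")
print("-> the simulated female effect is detected; the male effect is null.")

bb, bw, p_eq = tf.between_within_test(geno_groups, s1.params, "rsX")
print(f"\nstratification check: beta_between={bb:+.3f} "
      f"beta_within={bw:+.3f} equality p={p_eq:.2f}")
print("-> between and within components agree: no stratification signal,")
print("   as expected in a single homogeneous population.")
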