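"""Satorra-Saris power analysis of the genotyped-sample designs.

Reconstructs the adult female genotyped sample (853 unique genotypes,
89 MZF pairs, per-occasion participation from the published counts) and
computes the smallest SNP effect, expressed as percent of latent-trait
variance, detectable with 80% power at alpha = 0.01 — for the longitudinal
five-occasion factor model and for a univariate single-occasion comparison.
"""

from twinfactor.designs import adult_reference_design
from twinfactor.power import (min_detectable_ve, monte_carlo_power, ncp_power,
                              univariate_design)

design = adult_reference_design("f", seed=0)
print(f"adult female design: {design.n_unique_genotypes():.0f} unique genotypes")

ve = min_detectable_ve(design)
print(f"multivariate minimum detectable VE at 80% power: {ve:.2f}%")

uni = univariate_design(design)   # one survey occasion per person
ve_uni = min_detectable_ve(uni)
print(f"univariate   minimum detectable VE at 80% power: {ve_uni:.2f}%")
print("-> the longitudinal design detects a clearly smaller effect than a")
print("   single-occasion analysis of the same sample.")

r = ncp_power(design, 0.02)
print(f"\npower to detect a SNP explaining 2% of latent variance: "
      f"{r.power:.2f} (NCP {r.ncp:.1f})")
mc = monte_carlo_power(
    design.__class__(families=design.families[:200], params=design.params,
                     maf=0.5, alpha=0.01, df=1, test_sex="f",
                     free_correlations=False),
    0.05, n_reps=200, seed=1)
print(f"Monte-Carlo cross-check on a down-scaled roster at VE=5%: "
      f"rejection rate {mc.power:.2f}")
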