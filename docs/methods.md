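# Methods

## Model

A single latent anxious-depression (A/D) factor per person explains the
covariance among repeated A/D measures. For person *i* (sex *s*) at
indicator *t*:

    y_it = mu_t + beta_age * age_it + beta_sex * sex_i
           + lambda_ts * (F_i + beta_snp_s * g_i) + eps_it

with Var(F_i) = 1 (identification constraint; the loadings carry the
scale). The latent factors of relatives are correlated with a directly
parameterized correlation matrix: MZ and DZ twin correlations by sex plus
an opposite-sex DZ correlation, four parent-offspring correlations, and a
spousal correlation. Twin-sibling and sibling-sibling pairs reuse the DZ
correlation of the matching sex pairing, since same-age and ordinary
siblings are genetically equivalent. Positive semi-definiteness is checked
at evaluation (a failing step is rejected by the optimizer via a -inf
log-likelihood) rather than enforced by an unconstrained reparameterization,
so every estimate remains directly interpretable as a familial correlation.

**Cohort schemas.** Adults: one score per survey occasion (1991, 1995,
1997, 2000, 2002); twins eligible at all five, parents only at the last,
siblings at the last three. Age and sex covariates act on every adult
observation. Children: seven indicators (mother and father ratings at ages
7/10/12, one adolescent self-report); age and sex covariates act only on
the self-report, as parent ratings are taken at fixed ages.

**Child residual structure.** Ratings of the same child by two parents,
and of two co-twins by the same parents, stay correlated beyond the
factor. The minimal structure producing both is one residual factor per
rating age that loads on the mother and father rating of a child with
loading `sqrt(rho_raters_a) * sd` and is correlated `rho_twin(a, zygosity)`
across co-twins; each rating keeps its own unique noise. The implied
residual covariances are `rho_raters * sd_mo * sd_fa` within a child and
`rho_twin * rho_raters * sd * sd'` across co-twins; the single adolescent
self-report carries its whole residual as its age factor. The simulator
draws from exactly this construction (factors and residual factors, never
the implied covariance matrix), so the agreement of empirical and implied
moments asserted in the tests is a genuine cross-check of both codepaths.

**SNP coding.** Dosage counts the minor allele; the SNP enters the mean
structure only. Familial correlations are therefore re-estimated in any
genotyped subsample (they absorb SNP-induced covariance), while a SNP never
alters within-group covariances. A member with a missing genotype call
keeps its phenotypes; only its SNP mean term is omitted. Sex is coded
0 = male, 1 = female; ages are centered at the sample mean of observed
ages when data tables are assembled, so occasion intercepts refer to an
average-aged participant.

## Estimation

Raw-data (FIML) likelihood: each family contributes the multivariate
normal log-density of exactly its observed entries under the implied
moments restricted to those entries. Families are grouped by
covariance-relevant structure (roles, sexes, zygosity, missingness
pattern); within a group the covariance is assembled once per parameter
value and all families are evaluated with batched linear algebra. When
every free parameter enters only the mean (the stage-2 situation), the
factorizations are computed once and cached.

Optimization is quasi-Newton (L-BFGS-B with finite-difference gradients);
variances are optimized on the log scale and correlations on the atanh
scale (rater-residual shares on the logit scale), reported on the natural
scale. Convergence follows the optimizer's relative function-reduction and
gradient criteria (ftol 1e-9, gtol 1e-5); non-convergence and boundary
solutions are reported on the result object, not raised. Standard errors
come from the numerically differentiated observed information at the
optimum, on the natural scale.

**Two-stage protocol.** Stage 1 fits intercepts, covariates, loadings,
residual structure and familial correlations on the total sample. Stage 2
freezes loadings and residual structure at the stage-1 estimates and
re-estimates occasion intercepts, familial correlations and the per-sex
SNP effects in the genotyped subsample. Intercepts are freed in stage 2 so
subsample mean shifts cannot masquerade as SNP effects; since both the
full and reduced stage-2 models free them, test degrees of freedom are
unaffected. Per-sex tests are 1-df LRTs by default (Wald optional), the
joint test has 2 df; p-values below 0.01 are flagged and no
multiple-testing correction is applied (all raw p-values are emitted).

**Between/within decomposition.** `beta * g_i` is replaced by
`beta_b * g_fam + beta_w * (g_i - g_fam)` with `g_fam` the mean dosage of
genotyped offspring; genotyped parents contribute their own dosage through
the between component. No sex difference is modeled here. The equality
`beta_b = beta_w` is a 1-df LRT; inequality signals population
stratification. The test is reported as undefined when no family has
within-family dosage variance (e.g. an MZ-pairs-only sample).

## Synthetic cohorts

The generator emulates the structure of the Netherlands Twin Register
survey cohorts: configurable counts of MZM/DZM/MZF/DZF/DOS twin pairs,
optionally with both parents and up to one brother and one sister (adult
cohort) or twin pairs only (child cohort). Genotypes: founders from
Hardy-Weinberg proportions, offspring by Mendelian transmission (latent
founders are synthesized for parent-less pedigrees so DZ/sibling dosage
correlations are still 0.5), MZ co-twins share one draw. Phenotypes come
from the generative model above; participation is thinned independently
per occasion and role (missing completely at random, matching the
ignorable-missingness assumption of FIML), with default rates set to the
published per-occasion participation fractions. Twin ages per occasion are
drawn around the published occasion mean ages with a family-level offset;
parents are offset ~28 years upward, siblings by up to ±5. Everything is
bit-reproducible given (configuration, seed).

What the generator does *not* emulate: item-level questionnaire structure,
linkage disequilibrium between SNPs, ascertainment or participation that
depends on the phenotype, age-varying loadings. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to their violation in real registry data.

**Default parameters** are the published values wherever a value was
published: loadings are square roots of the printed per-occasion
factor-variance fractions, latent twin correlations are the printed ones
(adults: MZ .69/.70, DZ .31/.30/.29; children: MZ .77/.74,
DZ .40/.43/.48). Values never published were fixed once as plausible
defaults and not revisited: parent-offspring latent correlations 0.25
(roughly half the additive variance of a ~70%-heritable trait, slightly
shrunk toward the printed DZ values), spousal correlation 0 (exposed as a
free parameter), children's residual-factor twin correlations 0.75 (MZ) /
0.55 (DZ) at ages 7-12 — large and only mildly zygosity-dependent because
the same informants rate both co-twins — and 0.30/0.15 for the self-report;
cross-rater residual shares (0.18, 0.06, 0.17 at ages 7/10/12) are derived
from the printed mother-father phenotypic correlations minus the factor
contribution, averaged over sexes.

## Power analysis

The Satorra-Saris route: for a target variance explained (VE), the SNP
effect is `beta = sqrt(VE / (1 - VE) / (2 p q))` — VE is defined as the
SNP's share of *total latent-trait* variance, `beta^2 2pq / (1 + beta^2
2pq)`, since the SNP acts on the factor. The alternative's implied moments
are laid out per family configuration x genotype configuration (exact
Hardy-Weinberg/Mendelian weights; MZ pairs share a genotype, DZ pairs have
dosage correlation 0.5 via parental enumeration). The null model (beta = 0,
free occasion intercepts and familial correlations, frozen measurement
structure) is fitted to those moments by minimizing the count-weighted ML
discrepancy, with intercepts profiled out in closed form (GLS) and the few
correlations optimized numerically. The minimized discrepancy is the NCP;
power is the noncentral chi-square tail beyond the central critical value
(df 1, alpha 0.01 by default), and the minimum detectable VE inverts that
curve by bisection to |power - 0.80| < 1e-4. The default hypothetical SNP
has MAF 0.5; under the VE parameterization results are insensitive to MAF
(verified as a test property). A Monte-Carlo route (simulate rosters, fit
by FIML, count LRT rejections) validates the NCP route within binomial
error; it is also how the type-I-error calibration of the LRT is measured.

**Reconstructed designs.** Only aggregates of the genotyped samples were
published, so the rosters use exactly that information set: adults — 520
male / 853 female unique genotypes with 42 / 89 complete MZ pairs, the
non-MZ remainder treated as unrelated singletons (the published power
analyses likewise considered only the number of unique genotypes);
children — 382 boys / 392 girls, 144 / 160 MZ pairs, the remainder as
complete same-sex DZ pairs. Per-occasion participation patterns are
assigned individual-by-individual at the published per-occasion rates
(each member keeps at least one occasion); the assignment seed shifts the
resulting thresholds only in the third decimal. The univariate comparison
design keeps the same people and genotype sharing but a single indicator
per person (last adult survey occasion; age-7 maternal rating for
children).

A known sensitivity: for the children's *univariate* design the latent-VE
convention matters a great deal, because the single indicator carries only
lambda^2 ~ 0.51 of the latent variance — the same design yields ~5.2% under
the latent-variance reading and ~2.7% if VE is read as a share of the
observed phenotype's variance. The multivariate thresholds are nearly
insensitive to this choice, and the multivariate-beats-univariate ordering
holds under both readings.

## Heritability

`falconer_h2` pools MZ and DZ latent-factor correlations by averaging and
applies a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ. When the
implied shared-environment share is negative (as for the adult
correlations) the AE fallback sets c2 = 0 and a2 = rMZ. This is a rough
moment estimator, not a fitted variance-decomposition model, and is
reported to the nearest ten percent.

## Numerical and scale choices

Problem sizes in the test suite are chosen to exercise every claim at
desk scale: moment cross-checks use 1e6 generative draws of one family
configuration; SNP-effect recovery uses 800 families; LRT size is
calibrated on 2000 null replicates of a 200-family roster; NCP-vs-Monte-
Carlo agreement uses 300-400 replicates per grid point. Normal-scores use
Blom's approximation `Phi^-1((r - 3/8)/(n + 1/4))` with tie ranks averaged
and a linear rescale to the input mean/SD, applied to the pooled total
sample before subsetting (a per-group option exists). LRT statistics that
come out negative within 1e-4 (optimizer tolerance) are clipped to zero;
larger negatives raise, signalling a refit. Degenerate inputs are handled
explicitly: monomorphic SNPs are in HWE by convention and untestable for
association; a recessive test without minor-allele homozygotes and a
between/within test without within-family dosage variance report NA with
a diagnostic.

## Known limitations

* The child model supports twin pairs only (no child siblings or parent
  phenotypes), matching the data layout it targets.
* MZ-pair deduplication for MAF/HWE keeps the first co-twin by ID sort; a
  flag disables deduplication.
* The recessive re-analysis reuses the additive machinery on recoded
  dosage; dominance variance is not modeled in the covariance.
* Power designs cover rosters expressible as family configurations; no
  sample-size solving beyond VE bisection.
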