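# Methods

This note documents the models, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Data model

Genotypes are diploid dosages of the reference allele (0/1/2, −1 missing)
for biallelic SNPs; populations are sampling localities. Allele-count
tables hold reference counts x_kl out of n_kl sampled alleles per
locality k and locus l. Geographic distances are great-circle (Earth
radius 6,371 km); environmental distances are Euclidean over z-scored
locality variables (elevation, mean annual temperature, mean annual
precipitation — consumed from the locality table, never extracted from
rasters here). Both distance matrices are standardized by their
off-diagonal standard deviations before inference and the constants are
kept to back-transform results, which improves MCMC mixing without
changing the model.

## Filter cascade

Rules run in a fixed order (order changes the per-rule counts, so it is
part of the contract): (1) drop individuals missing >30% of loci;
(2) drop loci missing in >25% of individuals; (3) drop loci with minor
allele frequency <0.05 **or** minor allele count <3 (the joint
keep-threshold convention of vcftools; skipped for the "secondary"
dataset); (4) drop sites with QUAL <30; (5) set genotypes with depth <5
missing; (6) drop sites whose reference-read fraction pooled over
heterozygotes is >0.75 or <0.25 (boundaries keep; sites without
heterozygote reads keep); (7) a strand-balance rule, off by default —
single-end RAD data carry no strand annotation, and enabling it without
one is an error; (8) drop sites with mapping-quality ratio outside
(0.9, 1.05) — skipped with a warning when the annotation is absent unless
`require_annotations` is set; (9) drop sites with QUAL below a quarter of
the summed site depth (the factor is configurable because the prose
convention "a quality score ¼ below its depth" is genuinely ambiguous;
0.75 gives the other reading); (10) flag sites whose *per-genotype mean*
depth exceeds 3×(mean depth)² and drop flagged sites unless QUAL exceeds
twice the summed site depth, dropping flagged sites above the 99.5th
depth percentile regardless.

Two scales appear in rule 10 deliberately. On summed site depth the
3×mean² threshold is unsatisfiable — any outlier large enough to cross it
drags the squared mean up faster than itself (the inequality
X > 3(c + X/m)² has no solution once 3c² exceeds m²/12-ish); per-genotype
mean depth is the scale on which the histogram heuristic this rule
replaces actually operates. The percentile cutoff replaces a "visually
identified asymptote" with a reproducible number.

The cascade is idempotent on realistic inputs (verified exactly on the
hand-built fixture) but not by construction: masking shallow genotypes
raises individual missingness, so a second pass can in principle drop an
individual that scraped through the first.

## Isolation by environment vs isolation by distance

Locus l has a latent locality-frequency vector

  f_l ~ N(μ_l·1, μ_l(1−μ_l)·Ω) truncated to (0,1)^K,
  Ω_ij = (1/α₀)·exp(−(α_D·D*_ij + α_E·E*_ij)^{α₂}) + δ·1[i=j],

with observed counts x_kl ~ Binomial(n_kl, f_kl). Priors: μ_l ~ U(0,1),
α₀ ~ half-normal(10), α_D, α_E ~ Exponential(1), α₂ ~ U(0,1], δ fixed at
10⁻⁶. This is a faithful completion of the verbal "spatially correlated
Gaussian process" description of the Bayesian IBE method it reimplements;
it is not a port of any existing code, and overdispersion extensions
(beta-binomial sampling) are out of scope. Truncation is enforced by
bound-rejection in the proposals rather than by normalizing the truncated
density; the neglected normalizer varies with the parameters only through
loci whose mass leaks outside (0,1), which is negligible at the
differentiation levels simulated here.

Sampling is blockwise Metropolis–Hastings compiled with numba: one joint
log-scale random-walk update of (α₀, α_D, α_E, α₂) per iteration (α₂ on
the raw scale, rejected outside (0,1]), then scalar updates of every μ_l,
then K-vector updates of every f_l. Per-locus quadratic forms are cached
via 1'Ω⁻¹f_l and f_l'Ω⁻¹f_l so μ updates are O(1) and f updates O(K²).
Non-positive-definite proposals are rejected, never raised. Step sizes
adapt every 100 iterations toward ~35% acceptance (inside the 20–70%
band) during the first 25% of the run and are frozen afterwards, so the
post-burn-in chain is a valid fixed-kernel sampler. Defaults are a
desk-scale 100,000 iterations thinned every 250; the literature-scale
2,000,000 is one config value away. A fixed seed reproduces the trace
exactly.

The headline summary is the posterior of the decay-rate ratio
back-transformed to raw units, (α_E/α_D)·(sd_D/sd_E); samples with α_D
below a floor (10⁻⁶ standardized) are floored and counted. With the
likelihood disabled the sampler targets the parameter priors alone — the
prior-recovery diagnostic used in the tests.

**Identifiability caveat.** On a straight transect where elevation
increases monotonically with position, D* and E* are perfectly
correlated and only α_D·D* + α_E·E* is identified: the ratio posterior
then reflects the prior, not the data. Recovery experiments therefore use
designs with elevations shuffled along the line (distance-matrix
correlation ≈ 0), where a planted ratio of 0 is recovered below 0.1 and a
planted ratio of 1 is covered by the central 90% interval. This is a
property of gradient designs, not of the sampler.

## Demographic model choice

Single population; "null" is constant size with per-locus θ, "growth"
adds a backward-in-time decay N(t) = N₀e^{−αt}. The coalescent engine
draws inter-event exponentials and applies the growth time
transformation t₁ = ln(e^{αt₀} + αw)/α (continuous in α at 0), places
mutations as Poisson(θ/2 × branch length) under infinite sites, and folds
the spectrum. It matches Watterson's E[ξ_i] = θ/i within Monte-Carlo
error and agrees with msprime per frequency class under growth (tests).
"Three-nucleotide loci" are honored as per-locus θ = 3× per-site θ on
unlinked, non-recombining loci; 50 loci per dataset.

Priors: θ ~ log-uniform on [0.1, 20] per locus, α ~ U(0, 10); both
config-exposed since no defensible point values exist a priori. Reference
tables default to 100,000 simulations (10,000 in the bundled experiments,
which already separate the models cleanly). Summaries are folded-SFS
proportions scaled by their median absolute deviation across the table;
monomorphic simulations keep their all-zero summary rather than being
resampled, which would distort the prior. Rejection accepts the
⌈tolerance × n⌉ closest simulations (tolerance 0.05); model choice pools
both tables, sets posterior model probabilities to acceptance shares, and
reports Bayes factors both ways (a zero-acceptance model yields a bound,
flagged). Leave-one-out cross-validation holds out simulated datasets and
tabulates the confusion matrix at tolerances {0.01, 0.05} with 100
pseudo-observed datasets by default — reading the ambiguous "tolerance
rates of 0.01, 0.05, and 100 simulations" convention as two tolerances
plus a pseudo-dataset count.

## Range-limit diagnostics

θ per locus and locality comes from unbiased expected heterozygosity
Ĥ = n/(n−1)·(1−Σp̂²) inverted through the infinite-alleles equilibrium
F = 1/(1+θ): θ̂ = Ĥ/(1−Ĥ); monomorphic loci give 0. The range-position
test regresses θ̂ on the locality's absolute elevation distance from the
mean sampling elevation with a random intercept per locus, ML-fitted
(statsmodels MixedLM), against the no-covariate null; 1-df LRT. A model
with *population* as a fixed effect alongside a population-level
covariate is unidentifiable, so the locus-random-intercept structure is
the resolution of that wording; the test's type-I error at nominal 0.05
calibrates within [0.03, 0.07] over 1,000 null simulations (40 loci × 6
localities, normal noise — i.e. under the model's own assumptions).

Wright's neighborhood size uses Rousset's regression of F_ST/(1−F_ST) on
ln(distance in km) over locality pairs: Nw = 1/slope. Negative F_ST
values are set to 0 before the transformation and a non-positive slope is
corrected to 0, making Nw infinite — the operational definition of
panmixia at the sampled scale. Same-locality pairs (distance 0) are
excluded upstream; ρ and σ are never separately estimated.

F_ST itself is the two-level Weir–Cockerham variance-component estimator
computed from allele counts, combined across loci as a ratio of sums;
negative estimates are preserved everywhere except inside the Rousset
correction. It equals an independent ANOVA oracle exactly on an
exhaustive enumeration of small tables.

## Synthetic data

The generator mirrors the inference model: μ_l ~ U(0.05, 0.95) (keeping
most loci above the MAF threshold), f_l from the same Ω, clamped to
[0.001, 0.999] in place of formal truncation (cheap, and distorts only
loci already at the boundary), genotypes Binomial(2, f), missingness
i.i.d. Bernoulli. Depth is negative-binomial (dispersion 5) around a mean
of 30 reads, allele depths split reads Binomial(DP, balance 1/0.5/0 by
genotype), site QUAL scales with summed depth, and a mapping-quality
ratio annotation is drawn inside the keep-band. Defaults (8 localities ×
10 diploids, 2,000 loci, 10% missingness, α₀ = 50, α_D = 0.5, α_E = 0)
emulate a weakly differentiated gradient population — global F_ST around
0.01, the order observed in real gradient RADseq studies of vagile
insects; layouts are straight-line transects with a fixed
elevation-to-climate mapping since no real coordinates are modelled.

What passing tests show: the estimators invert their own generative
model, the samplers target the distributions they claim, and the
pipeline's plumbing is deterministic under seeds. What they cannot show:
robustness to features the generator omits — linked loci, allele-sharing
from library artifacts, heterozygote excess or deficit (genotypes are
exactly Hardy–Weinberg given f), reference bias in depth, and non-random
missingness. In particular, systematically *negative* F_ST — common in
real RAD data with excess heterozygosity, and the mechanism behind
all-infinite neighborhood sizes in empirical studies — cannot arise under
independent binomial sampling: under exact panmixia the estimator's sign
is a coin flip, so "infinite Nw" holds in only about half of panmictic
synthetic replicates rather than in (nearly) all, and with no decay
signal at all the IBE ratio is unidentified rather than near zero. The
joint whole-pipeline test asserts the strict qualitative conjunction
anyway and documents the per-clause outcome in its failure message.

## Problem sizes and numerics

Bundled experiments run at: MCMC 100,000 iterations (recovery) or
20,000–50,000 (pipeline demos); ABC 10,000 simulations per model;
coalescent oracle 50,000 loci; LRT calibration 400–1,000 replicates —
sizes chosen so the whole suite reproduces on a single CPU in well under
half an hour while leaving every Monte-Carlo check at least ~3σ of slack.
Numerical details: covariances get a fixed 10⁻⁶ nugget and a Cholesky
positive-definiteness check; LD pruning is leftmost-first greedy within a
50-SNP window per contig (deterministic); PCA mean-imputes missing
dosages, centers (no scaling by default — the variance of a dosage is
informative), and is deterministic up to sign; MAD-zero axes flag no
outliers (warned); hypergeometric SFS projection is seeded, not
expectation-based, so spectra stay integer-valued.
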