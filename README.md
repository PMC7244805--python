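# gradientpanmixia

Tests of dispersal limitation across environmental gradients from
reduced-representation SNP data. The package asks the questions a
landscape genomicist asks of RADseq data sampled along an elevational
transect: is there population structure? does genetic differentiation
track *environmental* distance beyond *geographic* distance (isolation by
environment vs isolation by distance)? is the population at
drift–mutation equilibrium or recently expanded? and does genetic
diversity decay toward the range limits?

It implements, from a called VCF onward:

- **SNP filter cascade** (`gradientpanmixia.filtering`) — the standard
  RADseq post-calling rules in fixed order: individual and locus
  missingness, MAF/MAC, site quality, genotype depth, pooled allelic
  balance, strand, mapping-quality ratio, quality-vs-depth, and a
  high-depth outlier rule; a "secondary" variant skips MAF/MAC filtering
  for site-frequency-spectrum work.
- **Population-structure statistics** (`gradientpanmixia.popgen`) —
  genotype PCA with MAD-based outlier flagging, great-circle and z-scored
  environmental distances, LD pruning (r² ≤ 0.1), Weir–Cockerham F_ST
  (ratio of sums; negative values preserved), the folded SFS with
  optional hypergeometric projection, and per-locus θ from mean
  homozygosity, θ̂ = Ĥ/(1 − Ĥ).
- **Bayesian IBE/IBD model** (`gradientpanmixia.ibe`) — latent allele
  frequencies f_l ~ N(μ_l, μ_l(1−μ_l)Ω) with
  Ω_ij = (1/α₀)·exp(−(α_D D*_ij + α_E E*_ij)^α₂) + δ·1[i=j],
  binomial counts, adaptive blockwise Metropolis–Hastings, and the
  posterior of the back-transformed ratio α_E/α_D — the relative
  contribution of environment to genetic differentiation.
- **Coalescent ABC** (`gradientpanmixia.demography`) — a numba-compiled
  coalescent simulator for constant-size and exponential-growth
  demographies (time transformation t₁ = ln(e^{αt₀} + αw)/α), rejection
  ABC on MAD-scaled folded-SFS proportions, Bayes factors from pooled
  acceptance shares, and leave-one-out cross-validation.
- **Range-limit diagnostics** (`gradientpanmixia.rangelimits`) — a
  1-df mixed-model LRT of per-locus θ against distance from the mean
  sampling elevation, and Rousset's regression of F_ST/(1−F_ST) on
  ln(distance) giving Wright's neighborhood size Nw = 4πρσ² = 1/slope
  (infinite when the corrected slope is ≤ 0, i.e. panmixia at the sampled
  scale).
- **Synthetic data** (`gradientpanmixia.simulate`) — seeded gradient
  designs and annotated VCF fixtures whose generative model mirrors the
  IBE inference model exactly, so parameter recovery is a closed loop.

The inferential stages follow a Model/Results convention: `IBEModel`,
`DemographicABC`, `ThetaRangeLimitModel` and `RoussetRegression` are
constructed from data and `fit()` returns a results object with
estimates, uncertainties and a `summary()`.

## Worked example

```python
import gradientpanmixia as gp

# an 8-locality transect from 730 to 1950 m, 10 beetles per locality
loc = gp.make_gradient_design(8, 730, 1950, spacing_km=1.0, n_per_locality=10)
cfg = gp.SimConfig(seed=5, n_loci=800, alpha_D=0.5, alpha_E=0.0)
gp.simulate_dataset(loc, cfg, vcf_path="data.vcf")
loc.write_tsv("localities.tsv")

genotypes, report = gp.apply_filter_cascade("data.vcf")
print(report.to_frame().tail(3).to_string(index=False))
counts = gp.tally_alleles(gp.ld_prune(genotypes))
dist = gp.distances_for(loc)
res = gp.IBEModel(counts, dist).fit(iterations=20_000, thin=100, seed=1)
r = res.ratio_summary()
print(f"IBE/IBD ratio: {r['mean']:.3f} +/- {r['sd']:.3f}")
```

prints (numbers from this exact seed):

```
                 rule  n_dropped
mapping_quality_ratio          0
     quality_vs_depth          0
  high_depth_outliers          0
IBE/IBD ratio: 0.846 +/- 1.235
```

The filter report shows no sites lost to the depth/quality rules on this
clean fixture (34 of 800 sites fall to the MAF/MAC rule earlier in the
cascade), and the ratio posterior sits near 1 with a spread larger than
its mean: on this
*collinear* transect elevation and geography are perfectly confounded
(Pearson r = 1 between the distance matrices), so only the *sum* of the
two decay rates is identifiable and the ratio stays prior-dominated — the
fundamental caveat of gradient designs. On designs where elevation is
decorrelated from geography the same model pins a planted ratio of zero
to below 0.02 (see `tests/test_acceptance.py`).

Or from the shell:

```sh
gradientpanmixia simulate --out-dir demo --n-loci 800 --seed 5
gradientpanmixia run --config demo.yaml
```

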