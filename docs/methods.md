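# Methods

## Model

`fishcast` fits a two-part hurdle model of community CPUE. The occurrence
submodel is a multivariate probit over all hauls; the biomass submodel is a
Gaussian regression of log CPUE over the positive records only. Treating the
zeros as unobserved in the biomass submodel (rather than censored) is what
makes the hurdle "true": zero inflation is produced and absorbed entirely by
the occurrence process, and the synthetic-data generator follows the same
factorisation.

Both submodels share one hierarchical architecture. For species *j* with
design row *x_i* (intercept, standardized covariates, squared standardized
depth and bottom temperature) and latent factor values *f_i*:

* occurrence: `z_ij = x_i'β_j + f_i'λ_j + ε_ij`, `ε ~ N(0,1)`, `y_ij = 1{z_ij > 0}`
* biomass: `log CPUE_ij = x_i'β_j + f_i'λ_j + ε_ij`, `ε ~ N(0, σ_j²)`, on occupied hauls

Coefficients have the matrix-normal prior `vec(B) ~ N(vec(Γ T'), W ⊗ V)`
with `W = ρ C + (1−ρ) I`. `C` is the Brownian-motion correlation implied by
an ultrametric taxon tree (shared root-path length divided by tree height),
`T` the species × trait-predictor matrix (intercept, standardized numeric
traits with fecundity logged, treatment-coded categoricals), `Γ` the trait
effects, and `V` the covariate-covariance. `ρ` measures phylogenetic signal
in the residual species responses.

The spatial random effect is a Gaussian predictive process: each factor is an
exponential-correlation GP (`k(d) = exp(−d/α)`) sampled at knot locations and
interpolated to haul sites by the conditional mean `A = C_sk C_kk⁻¹`; with
knots equal to sites the interpolation is exact. Knots come from seeded
k-means over haul coordinates in the equal-area plane (183 at survey scale;
fewer at desk scale). The number of factors is a fixed user setting
(`n_factors`, default 2, capped at 5) rather than an adaptive count: at the
problem sizes used here an adaptive birth/death scheme adds sampler
complexity without changing conclusions, and the multiplicative-gamma
shrinkage prior on loadings already damps surplus factors.

## Priors and sampler

* `V ~ InvWishart(p + 1, I)`; `vec(Γ) ~ N(0, 4 I)`;
  `σ_j² ~ InvGamma(2, 1)`.
* `ρ` is sampled on a uniform grid of step 0.01 over [0, 1]. A uniform grid
  prior (rather than an atom at zero) keeps endpoint recovery symmetric:
  data generated at ρ = 0 or ρ = 1 place the posterior mode at the matching
  endpoint.
* Factor loadings: multiplicative-gamma shrinkage (a₁ = 2, a₂ = 3); spatial
  ranges α per factor sampled on a 10-point grid spanning 5–100 % of the
  domain extent.
* Updates per sweep: truncated-normal latent scores (occurrence); joint
  Gaussian update of all species' coefficients under the Kronecker prior
  (block precision `W⁻¹ ⊗ V⁻¹` plus per-species `X'X/σ²`); conjugate Γ and
  V; griddy-Gibbs ρ via the eigendecomposition of C; per-species loading
  updates; per-factor knot-value updates with griddy α; conjugate σ².
  Per-species term masks (e.g. excluding sea ice for strictly temperate
  species) are imposed by conditioning the joint coefficient draw on zeros —
  rows/columns of the posterior precision are dropped, which is exact.

Two MCMC shapes are built in. `McmcConfig.desk()` (2 chains × 250 samples,
thin 5, burn-in 500) is the default used by the tests and the acceptance
script; it converges (mean PSRF < 1.1) on the synthetic systems shipped
here, which are far smaller than a real survey. `McmcConfig.paper_scale()`
(4 × 250, thin 500, burn-in 62 500) reproduces a survey-scale run shape and
is hours of compute. Gelman–Rubin PSRF is computed for coefficients, trait
effects, ρ, the diagonal of V and σ; factor loadings are excluded because
their sign/order is not identified.

## Synthetic data

The generator emulates the statistical structure of a shelf trawl survey and
its environmental stacks, not any particular sea:

* 0.25° grid with smooth bathymetry clipped to (10, 500] m; equal-area
  Lambert azimuthal coordinates (spherical formula, R = 6371 km) for all
  distances and areas.
* Seven covariates with latitudinal gradients plus spatially correlated
  noise; sea ice a declining logistic function of bottom temperature,
  clipped to [0, 1]; 25 projection periods (present = 2010 baseline, then
  2030–2100 every decade × three scenarios warming linearly to
  +1.6/+2.6/+4.5 °C by 2100); monthly survey-era stacks with a sinusoidal
  temperature season for haul extraction.
* Pure-birth ultrametric trees with exponential branch times and a stem
  branch (so any pair shares ancestry); traits drawn from typical demersal
  fish ranges with zoogeography tied to a thermal-affinity latent.
* Hauls placed uniformly over cells with within-cell jitter; months from a
  configurable survey calendar (default Jan–Mar); gear labels split by
  latitude. Catches follow exactly the model above; optional bell-shaped
  temperature niches (`temperature_optima`, width in °C) overwrite the
  temperature response for directional experiments. All true parameters are
  returned (`TrueParams`), and `simulate_community` also returns the design
  it generated from so fits are evaluated on the same standardization.

Not emulated: gear selectivity, effort variation, coastline geometry,
temporal autocorrelation of recruitment, and observation error beyond the
model's own noise — so passing recovery tests demonstrates correctness of
the inference machinery, not robustness to real-survey misspecification.

## Numerical choices

* VIF screening removes the highest-VIF covariate while any VIF ≥ threshold
  (default 4); ties remove the later column; constant columns are removed
  first with a warning.
* Rarity filters are strict: species seen in fewer than 100 hauls **or**
  fewer than 10 years are dropped, after removing hauls deeper than 500 m.
* Standardization constants are frozen at design construction and reused for
  every projection grid and cross-validation split.
* Hurdle combination multiplies occurrence probability with the Gaussian
  log-CPUE prediction per posterior draw and averages the products
  (`combine="expected_cpue"` gives the arithmetic-scale alternative
  `p·exp(g + σ²/2)`). The zero threshold is half the species' minimum
  positive recorded CPUE; values strictly below are zeroed, ties retained.
  Presence uses `probability ≥ max-TSS threshold` (ties present); the TSS
  maximiser is evaluated at all distinct predicted probabilities, smallest
  on ties.
* Core range: 90th percentile (linear interpolation) of present-day positive
  biomass; core cells are those at or above it **within the binarised
  range**, which guarantees core ⊆ range.
* MESS uses the strict-below empirical percentile formula with minimum
  aggregation across covariates; a zero-range training covariate contributes
  0 at its value and −10⁶ elsewhere.
* Variance partitioning normalises each covariate group's partial-predictor
  variance (plus the spatial effect's) by their sum, per draw and species —
  the convention that keeps fractions non-negative and summing to one even
  under correlated covariates; a covariance-based attribution would not.
* Fragmentation uses 8-connected raster components (diagonal corridors do
  not split a range); inter-polygon distance is the minimum cell-centre
  distance per component pair, averaged over pairs.
* Rates of change are OLS slopes against period year (present anchored at
  2010); percentage rates divide by the present value and are missing when
  it is zero. Trait regressions drop the least-significant term (categorical
  dummies as an F-tested block) until all p < 0.05. The signed-rank test is
  exact for n ≤ 25 without absolute-value ties, otherwise the normal
  approximation with tie correction.
* Cross-validation partitions hauls (not records) into seeded folds and
  scores withheld hauls from fixed effects only — the same exclusion of the
  spatial random effect applied to scenario projections; species are
  retained for biomass analyses iff mean CV-R² > 0.05 (strict).
* Cholesky jitter 1e-8 on spatial correlation matrices; probit latent draws
  use clipped inverse-CDF sampling, stable to |linear predictor| ≈ 8.

## Limitations

* Spatial prediction at *new* sites with the random effect is not
  implemented (projections deliberately exclude it); `include_spatial=True`
  is only available at the fitting hauls.
* Posterior draws are held in memory; no on-disk posterior store.
* The biomass submodel assumes a shared σ_j per species and no
  haul-level dispersion effects.
* The desk-scale MCMC shapes are sized for the shipped synthetic systems;
  survey-scale data need the long run shape and correspondingly more
  compute.
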