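# fishcast

Hurdle joint species distribution modelling of marine fish communities, with
climate-scenario projection and range-shift metrics.

## The problem

Bottom-trawl surveys record catch per unit effort (CPUE, fish/min) for many
species at once, with a large excess of zeros: most species are absent from
most hauls. Projecting how such communities redistribute under ocean warming
requires a model that (i) handles the zeros, (ii) lets rare species borrow
niche information from their relatives, and (iii) separates environmental
filtering from residual co-occurrence. `fishcast` implements the full chain
from survey records to range-shift statistics for shelf fish communities of
the kind sampled from the North Sea to the Barents Sea, and ships a
generative twin of the model so every stage can be validated against known
ground truth.

## The model

A two-part hurdle, fitted as a hierarchical joint species distribution model
(the HMSC family) by blocked Gibbs sampling:

* **Occurrence** — probit regression on presence/absence of every haul:
  `P(y_ij = 1) = Φ(x_i' β_j + f_i' λ_j)`, sampled with truncated-normal
  latent-score augmentation.
* **Biomass** — Gaussian regression of `log CPUE` on the same covariates,
  fitted to the positive records only (a true hurdle).
* **Species coefficients** — `vec(B) ~ N(vec(Γ T'), W ⊗ V)` with
  `W = ρ C + (1 − ρ) I`: the prior mean is trait-predicted (`Γ`, traits `T`),
  cross-species correlation per covariate mixes the phylogenetic correlation
  matrix `C` with the identity through the phylogenetic-signal parameter
  `ρ ∈ [0, 1]` (sampled on a 0.01 grid), and `V` is the covariate covariance
  (inverse-Wishart).
* **Spatial random effect** — latent factors `f` follow a Gaussian predictive
  process: exponential-correlation Gaussian processes evaluated at knot
  locations (k-means over haul coordinates, 183 knots at survey scale) and
  carried to hauls by the conditional-mean interpolator. Loadings carry a
  multiplicative-gamma shrinkage prior.

Covariates (bottom temperature, sea ice, currents, oxygen, phytoplankton,
depth) are VIF-screened at 4, standardized, and depth and temperature enter
with quadratic (bell-shaped) terms. Projections onto scenario grids
(SSP1-2.6/SSP2-4.5/SSP5-8.5, +1.6/+2.6/+4.5 °C by 2100; 25 periods including
the 2010 present) use fixed effects only, multiply occurrence probability
with the Gaussian log-CPUE prediction, zero the result below half of each
species' minimum recorded CPUE, and binarise occurrence at the per-species
max-TSS threshold. Derived metrics: expected richness (sum of occurrence
probabilities), relative dominance, range / biomass / core range (present-day
90th biomass percentile) / core biomass with OLS rates of change, centroid
shifts (km/yr north and east, equal-area Lambert plane), raster
fragmentation, backward-selected trait regressions, and Wilcoxon signed-rank
shift tests.

## Worked example

```python
import fishcast as fc
from fishcast.synthetic import CommunityConfig
from fishcast.model import McmcConfig

grid = fc.make_grid(nlon=12, nlat=10, seed=0)        # 0.25° shelf grid, ≤500 m
env = fc.simulate_environment(grid, seed=1)          # present + 8 decades × 3 SSPs
tree = fc.simulate_tree(8, seed=2)                   # pure-birth ultrametric tree
traits = fc.simulate_traits(tree.species, seed=3)
cfg = CommunityConfig(rho=0.7, n_factors=0,
                      covariates=("bottom_temperature", "depth", "oxygen"),
                      quadratic_for=("bottom_temperature",))
survey, truth, design = fc.simulate_community(env, tree, traits, cfg,
                                              n_hauls=400, seed=4)

model = fc.HurdleJSDM(survey, design, tree, traits, n_factors=0)
results = model.fit(McmcConfig(n_chains=2, samples_per_chain=150,
                               thin=2, burn_in=300, seed=5))
print(results.summary())
```

```
Hurdle joint species distribution model
========================================
hauls: 400   species: 8   terms: 5   latent factors: 0
chains: 2   samples/chain: 150   thin: 2   burn-in: 300
occurrence: rho = 0.54 [95% CI 0.03, 0.98]
biomass: rho = 0.50 [95% CI 0.02, 0.98]
mean PSRF = 1.001 (converged)
```

The posterior of the phylogenetic-signal parameter brackets the generative
value (`truth.rho_true = 0.7`; eight species give a wide interval), and the
mean potential scale reduction factor is below the 1.1 convergence bar.
Projection and metrics then chain off the results object:

```python
report = fc.explanatory_fit(results)                 # per-species AUC, R², TSS thresholds
cube = fc.project_cube(results, env, survey, report.thresholds)
rich = fc.richness_map(cube)
```

which prints, for this run, a mean in-sample AUC of 0.807, mean biomass R²
of 0.839, and mean expected richness rising from 4.59 species per cell at
present to 4.93 under SSP5-8.5 in 2100 as warm-water species expand
(species `sp01`'s binarised range grows from 20 825 to 30 085 km²).

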