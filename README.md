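# mothtails

Macroevolutionary analysis of an elaborate anti-predator trait: the hindwing
tails of moon moths (*Actias* + *Argema*, Saturniidae) deflect echolocating
bat attacks, and their length varies severalfold across the clade. This
package tests whether tail length tracks bat predation pressure and is
constrained by climate, by combining four pieces:

1. **Antenna-based photo calibration** (`mothtails.morpho`). Most
   community-science moth photos lack a scale bar. Within a photo every
   length shares one unknown pixel factor, so the male antenna works as an
   internal scale bar:

       adjusted length = length / (antenna / species mean antenna)

   with species antenna means taken from calibrated (scale-bar) photos.
   Validation: a Pearson screen that antenna length is nearly independent of
   body size, and per-species Wilcoxon rank-sum tests (exact enumeration for
   small samples, tie-corrected normal approximation otherwise) that adjusted
   and calibrated lengths agree.

2. **Predation-pressure surfaces** (`mothtails.predation`). Large aerial
   insectivorous bats are selected from a taxonomy table by three nested
   50%-majority rules; each selected species' clog-log SDM suitability
   surface is converted to a density surface by allocating its population
   total proportionally to suitability (cell densities sum back to the
   population exactly), and densities are summed into a total
   predation-pressure raster. Covariates are extracted at moth occurrence
   points by containing-cell lookup.

3. **Phylogenetic mixed models** (`mothtails.pglmm`). Adjusted wing length is
   modelled as y ~ N(Xβ, V) with V = σ²_phy Z C* Zᵀ + σ²_sp Z Zᵀ + σ²_e I,
   where C* is the unit-height Brownian-motion correlation of the phylogeny
   and Z maps observations to species. Covariates are centred and scaled.
   REML/ML estimation with Wald intervals is the primary route; a seeded
   Metropolis sampler supplies 95% credible intervals and DIC for model
   comparison, with VIF screening of collinearity.

4. **Comparative methods** (`mothtails.comparative`). On species means of the
   adjusted trait: maximum-likelihood fits of Brownian motion,
   Ornstein-Uhlenbeck and early-burst models compared by AIC, Blomberg's K
   with a permutation p-value, and BM ancestral state reconstruction by GLS.

Because the real study's archive is not an input, `mothtails.synth` generates
every input with known ground truth — birth-death trees, BM trait evolution,
climate-gradient rasters, Gaussian-niche suitability surfaces, and a
photo-measurement model with per-photo pixel factors — so all estimators are
testable against the parameters that generated the data.

## Worked example

```python
from mothtails import morpho, pglmm
from mothtails.comparative import blomberg_k, compare_evolution_models
from mothtails.pglmm import ModelSpec
from mothtails.synth import make_synthetic_study

study = make_synthetic_study(n_species=21, n_obs_per_species=10, seed=1)

means = morpho.species_mean_antenna(study.obs)        # from scale-bar photos
adj = morpho.add_adjusted_columns(study.obs, means)   # adds adj_hw, adj_fw

fixed = ("bat_abundance", "lgp", "precipitation", "temperature", "seasonality")
fit = pglmm.fit_pglmm(adj, study.tree, ModelSpec(response="adj_hw", fixed=fixed))
print(fit.beta.loc["bat_abundance"].round(3))

traits = adj[adj.has_scale].groupby("species")["adj_hw"].mean().to_dict()
print([(f.model, round(f.aic, 2)) for f in compare_evolution_models(study.tree, traits)])
k = blomberg_k(study.tree, traits, n_perm=1000, seed=1)
print(f"K={k.K:.3f} p={k.p:.4g}")
```

Output:

```
estimate    1.257
se          0.329
ci_low      0.613
ci_high     1.902
Name: bat_abundance, dtype: float64
[('BM', 150.95), ('OU', 152.13), ('EB', 152.95)]
K=0.745 p=0.01099
```

The bat-abundance coefficient is positive with an interval excluding zero
(the generator's true effect is 0.5 mm per covariate standard deviation; at
21 species the estimate is noisy but the sign and significance are
recovered). Brownian motion is the best-supported trait-evolution model, and
Blomberg's K near 0.75 with p ≈ 0.01 indicates strong phylogenetic signal in
the species means — the qualitative pattern the method is designed to
detect. On the same data the global mixed model reaches DIC 1240 against
1255 for the intercept-only model, and the BM root state is reconstructed at
70.6 mm (the generating root state is 70 mm).

A command-line interface mirrors the library: `mothtails simulate`,
`calibrate`, `surface`, `extract`, `fit`, `comparative`, and `mothtails run
--config cfg.yaml` for the full pipeline with a reproducibility manifest.

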