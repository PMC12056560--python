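# Methods

`mothtails` implements a macroevolutionary analysis of an elaborate
anti-predator wing trait — the hindwing tail of moon moths (*Actias* +
*Argema*, Saturniidae) — against bat predation pressure and climatic
constraint. The package covers the full chain from raw inputs to inference:
calibrating wing lengths from photos without a scale bar, converting bat
species-distribution-model (SDM) outputs into predation-pressure surfaces,
fitting phylogenetic mixed models of wing length on predation and climate
covariates, and continuous-trait comparative analyses on the species means.
Because the archived study data are not an input, a first-class synthetic-data
generator provides every input with known ground truth.

## Antenna-based scale calibration

Community-science photos report lengths in unknown per-photo pixel units. The
male antenna serves as an internal scale bar: within one photo every length
shares the same pixel factor, so

    adjusted length = length / (antenna / species mean antenna)

cancels the factor and returns millimetres. Species antenna means are computed
from scale-bar (calibrated) photos only — unscaled antennae are in arbitrary
units and cannot enter a millimetre mean — and from males only (females are
excluded throughout; the analysis models males, which are better represented
in collections and more exposed to bat predation). The adjustment is applied
to calibrated photos as well, so no species is biased by its mix of photo
sources.

Validation statistics:

* a Pearson screen that the proxy (antenna length) is nearly independent of
  body size (forewing length), per species and pooled, on calibrated rows;
* per-species two-sample Wilcoxon rank-sum tests comparing adjusted lengths
  from unscaled photos with raw calibrated lengths. The implementation uses
  midranks for ties, exact enumeration of all C(n1+n2, n1) assignments when
  max(n1, n2) <= 8 (two-sided by counting |W - E W| at least as extreme, so
  identical samples give p = 1), and the tie-corrected normal approximation
  with a 0.5 continuity correction otherwise.

## Predation-pressure surfaces

Predator taxa are selected by three nested passes over a bat taxonomy table:
families in which at least half of genera are aerial-insectivore genera
(a genus qualifying when at least half its species are aerial insectivores);
within those, genera in which at least half the species are aerial
insectivores of mean mass >= 10 g overlapping the moths' ranges; then the
species meeting that same conjunction. Both thresholds are parameters.

Surfaces are ESRI ASCII grids on a shared geotransform, assumed already on
the SDM's clog-log output scale in [0, 1]. Richness is the cellwise sum of
suitabilities (nodata propagates only where all inputs are nodata). A
species' density surface allocates its population total over cells
proportionally to suitability — `density = suitability * population /
sum(suitability)` — so cell densities sum back to the population exactly;
total predation pressure is the cellwise sum of densities. Grid registration
must match exactly: resampling is out of scope and a silent interpolation
would break the conservation property. Point extraction uses the containing
cell with half-open intervals (a point on a shared edge belongs to the cell
to the east/south); nodata extracts as missing, out-of-extent points produce
per-point error records.

## Phylogenetic mixed model

Observation-level adjusted hindwing (or forewing) length is modelled as

    y ~ N(X beta, V),   V = s2_phy Z C* Z' + s2_sp Z Z' + s2_e I

where Z maps observations to species and C* is the Brownian-motion
correlation matrix of the time-calibrated tree scaled to unit height, so
s2_phy and s2_sp are on the same (mm^2) scale. Fixed covariates (bat
abundance, length of growing period, precipitation, temperature, temperature
seasonality, optionally latitude and interaction terms) are centred and
scaled by the sample standard deviation (n-1) before fitting; an interaction
"a:b" is the elementwise product of the scaled parents, itself re-scaled.
Collinearity is screened with VIFs (OLS of each covariate on the others plus
intercept); the pipeline warns, but does not abort, at VIF >= 3.

Variance components are estimated by REML (default) or ML over the two log
variance ratios (s2_phy/s2_e, s2_sp/s2_e) with the error variance profiled
out in closed form; the optimizer is Nelder-Mead from five spread starts plus
explicit boundary candidates with either or both ratios at zero, so the fit
collapses exactly to OLS when the data carry no random-effect variance. All
likelihood evaluations use the Woodbury identity, reducing the cost per
evaluation to a Cholesky factorization at the number of species rather than
observations; the result is algebraically identical to the dense Gaussian
likelihood (tested to 1e-8). beta is the GLS solution at the optimum with
Wald 95% intervals; AIC uses the ML log-likelihood with k = p + number of
free variance components.

Primary inference is REML + Wald. A random-walk Metropolis sampler
reproduces Bayesian outputs — equal-tailed 95% credible intervals and the
DIC — because the original analysis was fitted in a Bayesian framework. The
sampler works on (beta, log sd components) jointly, with a correlated beta
proposal built from the Cholesky factor of the Wald covariance and a single
global scale adapted toward 30% acceptance during burn-in only (so the chain
after burn-in is a fixed Markov kernel). Priors are flat on beta and
half-normal on each standard deviation with scale five times the REML
estimate, floored at 5% of sd(y) so a boundary REML estimate of zero does not
degenerate the prior; these priors are a declared convention, not a
reproduction of the original ones, which are unstated. The DIC uses the
marginal (random-effects-integrated) deviance, D = -2 log N(y; X beta, V);
DIC = 2 mean(D) - D(posterior mean). Conditional DIC is not offered.

r-squared follows the marginal/conditional convention:
`r2_marginal = var(X beta) / (var(X beta) + s2_phy + s2_sp + s2_e)` and the
conditional version credits both random-effect variances in the numerator.
The original paper's predictive r2 definition is not reproduced; this is the
documented stand-in.

## Comparative methods

Species-level traits are the mean adjusted hindwing length over calibrated
specimens only (mean, not median — a declared choice). Three trait-evolution
models are fitted by maximum likelihood, each Gaussian with mean z0 * 1:

* **BM**: Cov_ij = s2 * t_mrca(i,j);
* **OU** (fixed root, single optimum = z0):
  Cov_ij = s2/(2a) * exp(-a d_ij) * (1 - exp(-2a t_mrca));
* **EB**: Cov_ij = s2 * (exp(r t_mrca) - 1)/r with r <= 0 and the r -> 0
  limit equal to BM.

z0 and s2 are profiled in closed form given the shape parameter; alpha is
searched on a log grid with alpha * height in [1e-4, 100] and r on a linear
grid in [-10/height, 0], each refined by a bounded scalar optimizer.
Covariances are evaluated with expm1 so the alpha -> 0 and r -> 0 limits are
numerically exact; non-positive-definite proposals are rejected, not fatal.
AIC uses k = 2 (BM) or 3 (OU, EB). Stationary-root OU is not offered.

Blomberg's K is the observed ratio of the mean squared error around the GLS
phylogenetic mean to the error under the tree's BM expectation, divided by
its expectation under BM (K near 1 under BM). The p-value permutes tip
labels (default 1000 permutations, seeded, with the +1 correction so p > 0).
Ancestral states under BM are the joint ML values — equivalently the
conditional expectation given the tips — computed by GLS with the tip-node
covariance; the root state equals the phylogenetic mean exactly. A 1e-12
diagonal tolerance absorbs zero-length terminal branches.

## Synthetic-data generator

The generator defines the study conditions under which the package is
tested; it is first-class, tested code.

* **Tree**: crown-start forward birth-death simulation (default pure birth,
  rate 1) conditioned on reaching exactly n extant tips by retry; the present
  is placed uniformly within the waiting time to the next event so terminal
  branches are strictly positive. Generalized sampling of survivor trees is
  not needed at these sizes.
* **Environment**: four covariate rasters (mean annual temperature,
  temperature seasonality, annual precipitation, length of growing period)
  as affine latitudinal gradients plus smoothed Gaussian noise at 10% of the
  gradient's range by default.
* **SDM surfaces**: Gaussian niche responses to the environmental layers
  with uniformly drawn optima and widths proportional to each layer's spread;
  population totals are lognormal(mu=10, sigma=1), i.e. a median of roughly
  2 x 10^4 individuals per species.
* **Observations**: for each species and observation at a uniformly sampled
  location, true hindwing length is z0 + u_phy + u_sp + X beta + e with
  u_phy ~ N(0, s2_phy C*), u_sp ~ N(0, s2_sp), e ~ N(0, s2_e), and the
  covariates (including extracted predation pressure) centred and scaled with
  the same operation the fitter uses, so the true betas are on the fitted
  scale. Forewing is a fixed per-species allometric multiple of hindwing
  (uniform 1.8-2.4); the antenna is the species antenna mean (uniform
  25-40 mm) times 1 + N(0, antenna_cv). Photos lack a scale bar with
  probability `scale_bar_prob`; such rows report all three lengths times one
  lognormal(0, 0.5) pixel factor, so only within-photo ratios are meaningful.

Default truth: beta = (bat 0.5, lgp 0.3, precipitation -0.2,
temperature -0.2, seasonality -0.4) mm per covariate standard deviation;
s2_phy = 144, s2_sp = 4, s2_e = 1 mm^2; z0 = 70 mm. The large phylogenetic
variance (species sd 12 mm around a 70 mm root) mirrors the severalfold
spread of hindwing length across the real clade and is what makes the
antenna adjustment informative: per-photo antenna noise perturbs adjusted
lengths by roughly cv * length, so between-species signal must dominate it.

What the generator does **not** emulate: spatial autocorrelation in
residuals or any spatial clustering of occurrences (locations are uniform
over the raster extent), sexual dimorphism (males only), observation-count
imbalance between museum and community-science sources, SDM fitting error,
and image-level measurement processes. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
spatially structured residuals or biased sampling.

## Numerical and testing choices

* Problem sizes: parameter-recovery and coverage checks run 100 replicates
  at 40 species x 10 observations; trait-model selection checks use 50-tip
  trees; permutation calibration uses 1000 null datasets with 199
  permutations each. These desk-scale sizes keep the whole suite to a few
  minutes while leaving Monte-Carlo error well inside the asserted bands.
* Recovery and selection replicates use scale_bar_prob = 1 and
  antenna_cv = 0 so the fitted model is exactly the generative model; photo
  calibration noise is exercised by its own checks.
* Model-comparison decision rule: a plain "lower AIC" ordering between
  models differing by one parameter accepts a useless covariate with
  asymptotic probability P(chi2_1 > 2) ~ 0.16. Where a selection decision at
  a conventional error level is needed, the package's tests use the standard
  dAIC > 2 support threshold (equivalent to a likelihood-ratio test at
  alpha ~ 0.046).
* Determinism: every stochastic routine takes an integer seed;
  `numpy.random.default_rng` streams are never shared across components.
  Pipeline outputs carry no timestamps, so identical configurations and
  seeds give byte-identical result files.
* Degenerate inputs: constant covariates raise a zero-variance error rather
  than dividing by zero; exactly collinear covariates report infinite VIF
  with the offender named; all-zero suitability surfaces make population
  allocation undefined and raise; a constant trait vector makes K undefined
  and raises.

## Known limitations

* The phylogeny is an input (or simulated); tree inference and divergence
  dating are out of scope, as are ancestral-range estimation, convergent
  regime detection and SDM fitting itself.
* The Metropolis sampler is adequate for the moderate dimensions used here
  but is not a general-purpose MCMC; heavy multimodality in variance
  components would require a better kernel.
* Wald and equal-tailed credible intervals assume the usual asymptotics;
  with very few species the phylogenetic variance is weakly identified and
  intervals for it should not be over-read.
* Latitude is accepted as an ordinary covariate when requested; no special
  treatment is given, and the spatial-correlation extensions available in
  some mixed-model software are not implemented.
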