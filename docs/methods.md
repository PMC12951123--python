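# Methods

`phylodecline` implements a complete comparative analysis of the correlates of
population decline in a species assemblage (anurans are the motivating case):
per-species geographic and climatic predictors are rebuilt from gridded
inputs, environmental prevalence summarizes how geographically common each
species' climate is, missing traits and trend labels are imputed with
phylogenetic information, and a Bayesian phylogenetic probit mixed model with
exhaustive DIC model selection and topology-ensemble validation estimates the
decline correlates. Because the real inputs (range polygons, global climate
rasters, a published mega-phylogeny) are external downloads, the package
ships a synthetic-world generator that produces all inputs with the same
statistical structure and known ground truth; every quantitative claim the
test suite makes is a property of the method checked against that ground
truth, not a reproduction of published point estimates.

## The decline model

For species *i* with binary trend *y<sub>i</sub>* (decline = 1, stable = 0):

    l_i = x_i' beta + u_i + e_i        e_i ~ N(0, 1)   (residual fixed)
    y_i = 1{l_i > 0}
    u ~ N(0, sigma2_p * A)

*A* is the phylogenetic variance–covariance matrix of the tree scaled by its
maximum diagonal entry, so an ultrametric tree gives a correlation matrix and
the phylogenetic variance `sigma2_p` is comparable across trees. The design
*x* holds the eight canonical predictors: log body size, log range size, and
z-scored absolute latitudinal midpoint, range-mean annual temperature (AMT),
temperature annual range (TAR), climate moisture index (CMI), and the
environmental prevalences of AMT and CMI. The two log columns are centered
(constants stored); this only relocates the intercept and keeps coefficients
interpretable per e-fold change.

The model is exposed statsmodels-style: `PhyloProbitMM` (constructed from
arrays or via `from_dataframe` with a tree) and
`PhyloProbitMMResults` with `summary()`, `conf_int()`, `dic()`, `ess()` and
the raw thinned draws. A coefficient is reported significant when its 95%
equal-tail credible interval excludes zero.

### Sampling

The probit link admits Albert–Chib truncated-normal data augmentation, making
every conditional conjugate. Three details matter and are deliberate:

1. **Blocked (beta, v) update.** beta is drawn with the random effect
   analytically marginalized (the liability covariance
   `alpha^2 sigma2_v A + I` is diagonal in the eigenbasis of *A*, computed
   once), then *v* given beta. Updating them as separate blocks lets the
   liability scale random-walk between the two and mixes poorly.
2. **Parameter expansion.** `u = alpha * v`, with `v ~ N(0, sigma2_v A)`,
   `alpha ~ N(0, 4)` and `sigma2_v ~ InvGamma(1, 1)`, so
   `sigma2_p = alpha^2 sigma2_v`. This keeps mixing healthy when the variance
   is near zero.
3. **Scale group move.** Binary data identify the liability scale only
   through near-threshold observations. A generalized-Gibbs move rescales
   `(l, beta, v)` by a scalar drawn exactly from its conditional under the
   multiplicative group (`s^2 ~ Gamma(d/2, Q/2)` with *d* the state dimension
   and *Q* the sum of the scaled quadratic forms). The move targets the same
   posterior and removes the frozen direction; without it chains can drift
   monotonically to enormous variance and never return.

Per-iteration cost after the one-off eigendecomposition is two `n x n`
matrix–vector products — quadratic in the number of tips.

### Priors

Priors are weakly informative **on the probit scale**, where they carry real
information: with unit residual variance, liabilities beyond ±10 saturate the
probabilities, so coefficients and standard deviations far above that are
scientifically meaningless. Defaults: `beta ~ N(0, 2.5^2)` per coefficient —
the standard weakly-informative scale for standardized predictors in binary
regression, whose documented purpose is regularizing separation — with
working multiplier `N(0, 4)` and base variance `InvGamma(1, 1)`. This
matters: a species-level random effect can nearly separate a binary response,
and with an effectively flat coefficient prior the posterior concentrates on
that separation ridge (coefficients near the prior's own scale, variance
unbounded) — we verified this against an exact orthant-probability posterior
on a 12-tip case. The fixed unit residual variance and these priors keep the
posterior anchored to the data scale; at small sample sizes (n of order 100)
a degree of scale inflation remains visible and is a property of the model
class, not of the sampler. Coefficients are probit-scale; logit-scale
magnitudes are roughly 1.6 times larger.

### DIC and convergence

The deviance is conditional on the random effects,
`D = -2 sum log Bernoulli(y | Phi(x'beta + u))`; `pD = Dbar - D(posterior
means)` and `DIC = Dbar + pD`. Effective sample sizes use the
autocorrelation-sum estimator with Geyer's initial-positive-sequence
truncation; a constant sequence is defined to have ESS 1.

### Chain profiles

`full`: 1,000,000 iterations, 100,000 burn-in, thinning 500 — the
production-length settings for a real analysis. `test`: 50,000 / 10,000 / 20, used by the simulation
studies. `search`: 10,000 / 2,000 / 4, used to rank the 256 candidate models;
DIC rankings stabilize long before coefficient summaries, and the final and
ensemble fits always rerun at a full profile. All are configurable.

## Model selection and topology uncertainty

All 2^8 = 256 predictor subsets (including the intercept-only model) are
fitted on the identical complete-case species set — rows are dropped once, up
front, so deviances are comparable — and ranked by DIC. Models within 2 DIC
units of the best form the candidate set. Two tie-break policies exist:
`parsimony` (fewest predictors, then lower DIC) and `forced` (smallest-ΔDIC
candidate containing a user-named predictor list; this mechanizes the
practice of preferring the most informative model among statistically
equivalent candidates and is labeled as such in reports). The selected model
is refitted across an ensemble of perturbed topologies (seeded
nearest-neighbor interchanges plus lognormal branch jitter, standing in for a
posterior tree sample) and the thinned draws pooled with equal weight per
topology; the pooled mean, 95% interval, and significance flag propagate
phylogenetic uncertainty. Both the complete-case ("original") and the imputed
dataset run through the identical pipeline.

## Predictors from gridded data

The world is an equal-area grid (rows uniform in sin latitude, constant cell
area) with AMT/TAR/CMI layers and a land mask; a polar band is excluded from
all computations, mirroring the exclusion of Antarctica from real analyses.
Range size is cell count x cell area; species whose range is below one grid
cell keep their polygon-analogue area but have missing climate summaries,
which routes them into the imputation path. The latitudinal midpoint is the
unweighted mean of cell-center latitudes (equal-area grid = area weighting),
with the absolute value taken **after** averaging, so trans-equatorial ranges
get |lat| near 0; the alternative reading (mean of absolute latitudes) is
available via `lat_midpoint(..., absolute_first=True)`, not the default. Climate means skip NODATA cells. Body sizes
from two sources are averaged, with a >5-fold disagreement flagged for review
but still averaged (the flag is the generic mechanism for order-of-magnitude
database incongruences). Nearest-neighbor grid coarsening takes the fine cell
nearest each coarse center, ties toward the lower index.

## Environmental prevalence

Each climate variable is binned into 60 equal intervals over a fixed support
(AMT: -27 to 31 degC, width 58/60; CMI: -312 to 390 kg m^-2 month^-1, width
11.7), half-open with the last closed, out-of-range values clamped into the
extreme bins. The rare extreme bin — coldest for AMT, wettest for CMI — is
lumped into its neighbor; lumping merges adjacent bins (the alternative
reading, merging the two opposite extremes of one variable with each other,
is physically incoherent and was rejected). Prevalence is the fraction of
valid land cells per bin; a species' prevalence is the prevalence of the
post-lumping bin whose center is nearest its range-mean climate, ties toward
the lower bin. A range-overlap-weighted variant is exposed but not default.

## Phylogenetic imputation

Missing continuous predictors (body size on the log scale, AMT, TAR, CMI) and
trend labels are filled by iterative chained imputation. Features for every
target column are the leading phylogenetic eigenvectors (eigenvectors of the
double-centered squared patristic-distance matrix; default
`min(30, n_tips - 1)`), the current values of the other modeled columns, and
any complete auxiliary columns (the pipeline passes log range size and
absolute latitude, which carry most of the decline signal and are always
observed from the range polygons).
Continuous targets use ridge regression with the penalty chosen per column by
efficient leave-one-out cross-validation over a fixed grid — this matters:
with no signal the tuned penalty collapses predictions to the column mean
(predictive R^2 near 0), where any fixed small penalty overfits and produces
strongly negative R^2. The trend uses multinomial logistic regression over
{increasing, stable, decreasing}; "unknown" is a missing state, never a
predicted class. Iteration stops when imputed continuous values (z-scale)
change by less than `tol` (default 1e-3, max 10 iterations); non-convergence
returns a flagged result rather than an error. Observed cells are never
altered. Validation hides observed cells one at a time (optionally a seeded
subsample to bound runtime), re-imputes, and reports predictive R^2
(`1 - SSE/SST`, reported as computed, including negative values), plus a
confusion matrix, accuracy, and Cohen's kappa for the trend. The tree-based
learner of the original packaged imputer is replaced by this deterministic
linear/logistic learner by design: no stochastic fitting in the default path.

## The synthetic world

The generator defines the study conditions: a birth–death tree (birth 1.0,
death 0.3, rescaled to unit height), climate layers with
equator-to-pole temperature decline, latitude-increasing seasonality, and
autocorrelated moisture, all inside the prevalence binning supports; land is
a smoothed random field (fraction 0.4) with the polar band masked; contiguous
ranges grown by seeded 4-neighborhood expansion with lognormal target sizes
(log-mean 2.0, log-sd 1.2), 5% of species below grid resolution; log body
size evolves by Brownian motion (rate 0.6 on the unit-height tree, root at
log 50 mm). Trend labels come from the probit liability with the generating
coefficients and `sigma2_p = 1`; the default intercept (0.5) puts the
marginal decline fraction near 60% of assessed species, the real-data order
of magnitude; 0.5% of labels are recoded increasing and 25% unknown; body
size is hidden in 14% of species and moisture in a further 0.2%; threat
categories are an ordinal cut of the liability plus noise of twice the
residual scale (threat status is a lagging, noisy indicator), with a 10%
Data Deficient slice. A `TruthRecord`
stores every constant and sub-seed, and `regenerate` rebuilds the dataset
bit-identically. What the generator does **not** emulate: climate physics,
polygon geometry, spatially biased sampling effort, or taxonomic label error
— so green tests certify the statistical machinery under the model's own
assumptions, not robustness to those real-data pathologies.

## Numerical and policy choices

- Natural log for body size and range size.
- z-scoring constants always come from the full table once, so coefficients
  are comparable across model subsets and across original/imputed datasets.
- vcv matrices exclude any stem edge above the root; eigenvector signs fixed
  by the first-nonzero-positive convention; eigenvalues clipped at 1e-10
  before inversion; a singular correlation matrix is jittered by 1e-8 with a
  warning.
- Ties: nearest-bin and nearest-cell ties break toward the lower index.
- Missing values are NaN/NA sentinels end to end, never magic numbers.
- The pipeline derives one named sub-seed per stage from the master seed
  (SHA-256 of "stage:seed"), so identical configuration and seed give
  byte-identical outputs, and changing one stage's seed perturbs only
  downstream artifacts.

## Problem sizes

The default demonstration study is 200 tips on a 40 x 40 grid with a
10,000-iteration final chain, a 2,000-iteration search chain, 3 ensemble
topologies, and leave-one-out validation subsampled to 30 cells per column.
The simulation studies in the test suite use 300 tips at the `test` profile
for parameter recovery and model selection, 200 tips for imputation recovery,
and n = 1000 for the probit-limit check. These sizes are the package's own
demonstration conditions; the `full` profile provides the production-length
chain settings for real analyses.

## Known limitations

- Single imputation: no between-imputation variance reaches the fitter.
- DIC is conditional on the random effects; marginal-likelihood criteria
  (WAIC, cross-validation) are out of scope.
- The topology ensemble is a perturbation stand-in, not a posterior sample
  from sequence data.
- `sigma2_p` in threshold models is intrinsically weakly identified; its
  posterior is prior-sensitive, which is documented above rather than hidden.
- The association analysis uses the same MCMC engine as the decline model
  rather than a maximum-likelihood phylogenetic logistic estimator.
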