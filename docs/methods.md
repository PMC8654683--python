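# Methods

This note documents the models, the numerical choices behind them, what
the synthetic worlds do and do not emulate, and the problem sizes used by
the shipped experiments.

## 1. Usage model

**Model.** Survey record *j* contributes `k_j ~ Binomial(N_j, p)` at its
cell-year, with `logit(p_{s,t}) = x_{s,t}'β + w(s,t)`. The residual field
*w* is a zero-mean Gaussian process with separable covariance
`σ² · Matérn_ν(d; range) · ρ^{|Δt|}` — a Kronecker product of a stationary
spatial correlation and an AR1 year-to-year correlation. Conventions:

- `spatial_range` is the distance at which the Matérn correlation equals
  0.1 (a practical-range parameterisation; the internal lengthscale is
  solved numerically from it).
- `matern_nu` is fixed at 1 — the default smoothness for two-dimensional
  latent fields — and is not estimated; smoothness and range are barely
  separately identifiable at these data densities.
- β has a N(0, 5²) prior per coefficient, which regularises the fit under
  separation (all-0 or all-N surveys).

**Covariates.** Three child learners (penalised B-spline additive model,
gradient-boosted trees, elastic net) are fit to the empirical survey
proportions on the logit scale with N-weights, using five-fold
cross-validation grouped *by survey* so a survey never predicts itself.
Their out-of-sample predictions (logit scale) are the design columns of
the geostatistical model at data locations; refits on all data supply the
columns on the full prediction grid. This keeps the GP's residual field
honest: in-sample predictions of flexible learners would absorb it.

**Inference.** At fixed covariance hyperparameters the posterior of
`(β, vec(w))` is approximated by a Gaussian at its mode (Laplace
approximation), found by Newton iteration with backtracking line search;
the binomial Hessian is diagonal per data row, and the prior precision is
assembled from the Kronecker factors, so each Newton step is one dense
Cholesky solve of dimension `p + cells × years`. Hyperparameters maximise
the Laplace-approximate marginal likelihood over a grid:

- a coarse 5×5×5 grid spanning ±1.5 in log(range), log(σ) and atanh(ρ)
  around moment-based initial values (half the median pairwise distance of
  surveyed cells; the excess spread of empirical logits beyond binomial
  noise; ρ₀ = 0.5);
- one local refinement pass, 3×3×3 at half the coarse spacing around the
  incumbent. Without it the selected point cannot be closer to the truth
  than the 0.75-unit coarse spacing, which alone exceeds the recovery
  tolerances we test; with it, grid resolution is no longer the binding
  error.

Selected hyperparameters are the exhaustive argmax; the grid also yields a
likelihood-weighted posterior mean of the hyperparameters (uniform prior
over the grid span), which is what the recovery experiments report.
Uncertainty in p is propagated by 1000 joint Gaussian draws of `(β, w)`
pushed through the inverse logit.

Dense covariance handling caps worlds at 400 cells × 19 years; beyond
that the constructor raises rather than silently approximating.

**Aggregation.** Draws are aggregated to district, state and country as
population-weighted means per draw; means and percentile 2.5/97.5
intervals are computed only afterwards. Admin units with zero population
return NaN, never 0. Countries configured as having no modelled estimate
receive the median national mean of their region, flagged as imputed and
without an interval. The within-country inequality statistic is
`(district − national)/national`, summarised by its range.

## 2. DDD engine

Sales records (country, year, ATC code, route, sector, unit, quantity)
convert as: standard units × mg-per-SU → kilograms → `kg·1000/DDD_g(route)`
defined daily doses; records already in DDD pass through; mixed units
within a country-year are summed. Only codes starting `J01` (systemic
antibacterials) are kept. The registry is versioned user data (two CSV
snapshots, "pre-2019" and "2019"); raising a drug's DDD strictly lowers
the DDD computed from a fixed mass, which the tests assert as a
monotonicity property. Unknown routes resolve through a per-code default
route in the registry (oral if present, else parenteral). Combination
products are single entries with their own DDD; no active-moiety
splitting. Rates use `DDD / population / 365 × 1000`; the 365-day
convention ignores leap years (< 0.3%, constant across comparisons).

The registry snapshots cover 13 common J01 codes with plausible
route-specific values; they are editable fixtures for exercising the
machinery, not a reproduction of the WHO index.

## 3. Imputation

Chained-equation multiple imputation with regression trees: initialise
missing entries with random observed values; per sweep and target column
grow a variance-reduction tree (minimum leaf 5, no depth cap) of observed
rows on the predictors and redraw each missing entry uniformly from its
leaf's observed donors; `n_iter = 10` sweeps, `m = 5` independent chains
(both conventional defaults — no authoritative values exist). Donor draws
guarantee imputed values stay within the observed range and observed
entries are never touched; pooling is the cell-wise mean, with cells that
are identical across chains restored bit-exactly, and between-imputation
variance reported but not propagated (the high-income track carries no
uncertainty by design).

Applications: (a) hospital-sector DDD where only retail was observed,
predictors = retail DDD, population, year (+ optional covariates);
(b) missing high-income country-year rates, predictors = year, one-hot
region *and one-hot country* — without country identity, donors mix
countries within a region and scattered missing years cannot recover a
country's own level. Categorical predictors are one-hot encoded rather
than grouped exhaustively.

## 4. Consumption model (LMIC track)

**Stage 1** regresses observed log rates on national features — the
population-weighted national usage estimate plus national covariate means
— with the same three-child stack, folds grouped *by country*, and
combines children by non-negative least squares normalised to the simplex.
Predictions exist for every LMIC country-year.

**ST-GPR.** On the log scale, the stage-1 series is the GP prior mean and
the covariance over country-years is

`amp² · K_t(|Δt|; ℓ) · [(1−λ)·1{same country} + λ·1{same region}]`

with `K_t` Matérn-3/2, lengthscale ℓ = 5 years, and λ = 0.3 the
cross-country pooling weight within a GBD region. "Space" enters only
through region membership — consumption has no usable notion of distance
between capitals at this granularity. Exact Gaussian conditioning on the
observed rates (nugget floor: sd 0.05 log units per observation; the
experiments pass the simulation's known noise sd instead) gives the
posterior; 1000 joint draws exponentiated give rates and percentile
intervals. Degenerate cases: zero amplitude or no observations return the
prior (the latter with a warning); negative eigenvalues from cancellation
in the posterior covariance are clipped, not jittered, so degenerate
posteriors yield exactly constant draws.

Two choices matter for calibration and were made after their failure modes
were understood:

- the prior mean at observed rows uses the stage-1 **out-of-sample**
  combined prediction (full-fit rows elsewhere). In-sample predictions of
  the boosted child interpolate the observations, erasing the residual
  field and, worse, injecting overfit noise that the GP then pools across
  countries; measured symptoms were collapsed held-out coverage and
  smoothing that *hurt* at larger amplitudes.
- the amplitude is 1.4826 × MAD of those out-of-sample residuals
  (configurable constant override). On in-sample residuals the MAD
  collapses toward zero.

**Combination.** LMIC draws and imputed HIC point rates partition the
country set (with configured income overrides); volumes are
`rate × population × 365 / 1000`; regional and global rates are
population-weighted means computed per draw for the LMIC part with the
HIC part entering each draw as a constant — so global intervals reflect
LMIC uncertainty only, consistent with not attaching intervals to the
imputed HIC track.

**Cross-validation** holds out whole countries in five folds, refits both
stages, and scores out-of-sample log-RMSE and bias for stage 1 alone and
for the smoothed pipeline, plus 95% coverage of held-out observations
against the *predictive* interval (latent draws plus nugget noise — the
held-out quantity is a noisy observation, not the latent rate).

## 5. Class and AWaRe allocation

Class proportions are computed from pre-imputation totals only (imputed
hospital values would distort the class composition). Region fallback is
DDD-weighted — member countries' class DDD are summed then normalised —
not a mean of proportions, so large consumers dominate the regional
profile, which is what "the region's proportions" should mean physically.
Fallback is year-specific where the region has data in that year, with an
all-years pool otherwise; it is idempotent. Proportions multiply the mean
total rate only, so class and AWaRe tables carry no intervals and both
partition the total exactly (to 1e-9). Allocation classes are ATC level 3
plus registry-configured select level-4 classes (e.g. third-generation
cephalosporins J01DD, carbapenems J01DH, oxazolidinones J01XX).

## 6. Synthetic worlds: what they emulate, what they do not

Countries are contiguous rectangular blocks on a shared planar lattice,
split into contiguous states and districts; coordinates are cell centres
under Euclidean distance. Covariates are fixed low-order spatial
polynomials plus smooth cosine noise with linear year trends,
standardised. Populations are lognormal-smooth in space with a small
constant growth rate. The `floor(income_split × n_countries)` countries
with highest mean covariate are labelled high-income (deterministic floor
rule); regions group consecutive countries, super-regions group regions.

The latent usage surface is drawn through the **same covariance
constructor** the model fits with — generative/inferential symmetry is an
asserted test property, not a convention. Surveys: point records sample
cells population-weighted within a country (cluster sizes N uniform on
20–200, ten clusters per survey); polygon records aggregate five latent
clusters and keep only the district code. Sales records invert exactly
through the DDD engine to the ground-truth rates before missingness
(standard units with half-a-DDD product strength through 2013, kilograms
from 2014, mirroring a real audit format change); missingness then deletes
hospital records for a configurable share of countries and whole
high-income country-years. Ground-truth national rates are log-linear in
national covariates with a mild upward trend plus region-level (sd 0.25)
and country-level (sd 0.25) effects, clipped to 2–50 DDD/1000/day — the
span observed across real countries; the regional effect matters, because
regional clustering is precisely the assumption behind region pooling and
region fallback. The class mix is a Dirichlet draw (concentration 5) over
the registry's *allocation classes* — one vocabulary for both truth and
recovery — and the hospital share of sales is uniform on [0.1, 0.4].

Not emulated: survey design weights and stratification, caregiver
misreporting, informal-market sales, substandard/falsified medicines,
paediatric dose scaling, geodesic geometry. Passing tests therefore
demonstrate correctness of the estimation machinery under the models'
own assumptions at desk scale — not robustness to the biases of real
surveys and sales audits.

## 7. Experiment design and problem sizes

All experiments run single-CPU from one seed each.

- **Usage recovery/calibration** (20 replicates): 4 countries × 64 cells
  total... precisely 4 countries of 16 cells (64 cells), 12 years, ~60
  surveys (50 point × 10 clusters + 10 polygon), truth β = (0.5, −0.3),
  range 3 (lattice units), σ = 0.8, ρ = 0.7. Reported: grid-posterior-mean
  hyperparameters averaged over replicates (geometric mean for the
  positive ones), mean β z-scores, and pooled district-year 95% coverage.
  ~13 s per replicate.
- **End-to-end consumption recovery** (20 replicates): 48 countries of 4
  cells in regions of 4, 19 years, 60% of LMIC country-years observed with
  log-normal noise sd 0.1 (the known noise is passed as the nugget);
  scored as log-RMSE of smoothed means against ground truth.
- **Smoothing benefit / held-out calibration** (20 replicates): same
  48-country frame, truth generated from the model's own assumptions — a
  learnable log-linear mean plus a residual drawn from the ST-GPR kernel
  itself (amplitude 0.3, λ = 0.3) — then out-of-country cross-validation
  compares pipeline vs stage-1 RMSE and scores coverage. The 48/12-region
  frame is a scale-down of the real 204-country, 21-region frame chosen so
  the paired RMSE comparison has enough effective degrees of freedom to be
  informative.
- **Default pipeline**: 8 countries × 9 cells, 19 years, 1000 draws;
  runs in about a minute and is asserted to rerun bit-for-bit.

## 8. Known limitations

- Hyperparameter uncertainty is not propagated (draws condition on the
  selected grid point); district coverage sits slightly below the nominal
  95% for this reason and the calibration band (90–98%) accounts for it.
- The Laplace approximation is exercised against a closed-form oracle only
  under a Gaussian likelihood; for the binomial likelihood its quality is
  checked indirectly through recovery and coverage.
- Dense Kronecker algebra bounds world size; the production-scale sparse
  (SPDE-style) machinery is out of scope.
- The boosted and elastic-net children are order-stable but not
  order-equivariant (internal row-position splits), so exact permutation
  invariance holds only for the closed-form smoother child.
- Stage-1 out-of-sample predictions exist only at observed rows; the prior
  mean surface therefore mixes OOS and full-fit values across rows of an
  observed country, which is harmless under dense observation but is a
  seam worth knowing about.
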