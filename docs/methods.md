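# Methods

`amuplan` analyses farm-level antimicrobial usage (AMU) in broiler
production and turns the fitted model into farm-specific, cost-annotated
usage-reduction plans. This note documents the model, the procedure, the
tunable parameters and the numerical choices, and states what the
synthetic-data generator does and does not emulate.

## Outcome and covariates

AMU is measured as TIDDDvet — treatment incidence based on defined daily
doses per 1000 animal-days at risk; TIDDDvet/10 is the percentage of a
broiler's life spent under treatment (150 TIDDDvet = 15%). Farm-level
usage distributions are right-skewed with occasional extreme farms and a
handful of exact zeros, so the outcome is modelled on the started-log
scale

    z = ln(ti + 1),

which is finite at zero and strictly increasing; predictions are reported
back on the TIDDDvet scale via `exp(z) − 1`, with sub-zero transformed
predictions clamped to 0 (and logged). The transform lives in a single
function (`preprocess.transform_amu`) so an alternative started-log or
Box–Cox variant can be swapped in without touching the rest of the
pipeline.

The "null model" covariates — broilers per round, production rounds per
year, number of workers — are farm size/productivity proxies; broilers
and workers are natural-log transformed (outliers, rescaling), rounds per
year enters untouched.

Binary biosecurity answers are screened before modelling: a feature is
excluded if more than 10% of farms are missing it, or if the minority
level accounts for less than 15% of the non-missing answers (near-constant
survey items carry no usable signal at n≈180). Residual missingness is
kept as a third "missing" level of the answer (coded 2), which tree models
can route on; the level is imputed away (below) before effect sizes are
computed.

## Mixed-effects random forest

Farms are clustered in countries, so the regression forest is combined
with a country-level random intercept:

    y_ic = f(x_ic) + b_c + ε_ic,  b_c ~ N(0, σ²_b),  ε ~ N(0, σ²_e).

Fitting alternates (`mixrf.MixedForest.fit`):

1. fit the forest to `y − b` with the current intercepts;
2. compute out-of-bag residuals `r = y − f_oob(x)` — out-of-bag so the
   intercepts are estimated from signal the forest has not memorised —
   and update each `b_c` as its posterior (BLUP) mean given the current
   variance components;
3. update `σ²_b` and `σ²_e` from the posterior moments;

stopping when the largest intercept change drops below `em_tol`
(default 1e-4), after `max_em_iter` (default 50) iterations, or — the
case that matters in practice — when the update stops shrinking: each
refit perturbs the out-of-bag residuals by a roughly constant amount, so
the intercept change plateaus at that noise floor (∝ 1/√n_trees) rather
than decaying to zero, and once `max_delta` fails to fall below 95% of
the previous iteration's the loop stops. On well-conditioned data this
takes about five iterations; the per-iteration trace (variance
components, intercept movement) is kept on the results object. With a single country the model collapses to an
ordinary regression forest (σ²_b = 0 by construction).

Forest defaults mirror classical regression-forest practice: 500 trees,
`mtry = floor(p/3)` candidate features per split (7 for a 21-predictor
model), minimum leaf size 5. A single seed controls bootstrap resampling
and split tie-breaking. Gini importance is the forest's total
impurity-(variance-)decrease per feature, normalised to sum to 1.

Proximity between two farms is the fraction of trees in which they share
a terminal node, computed over all observations and all trees (the
classical definition; not restricted to out-of-bag pairs), giving a
symmetric matrix with unit diagonal and entries on the grid k/n_trees.

Predictions add a farm's country intercept when the country was seen in
training; unknown countries receive the population mean intercept 0. The
planner includes the intercept for known countries, since its comparisons
are within one farm.

## Recursive feature elimination

Feature selection is cross-validated backward elimination
(`rfe.run_rfe`):

1. k-fold CV (default 10), folds stratified by country so every training
   split contains every country — without this the intercepts of an
   absent country would be inestimable;
2. within each fold, fit on all features and repeatedly drop the single
   least Gini-important feature, refitting after each drop, until
   `floor(0.25·p0)` remain (53 features → 13);
3. count how often each feature survived across folds and form the nested
   subsets "appeared ≥ t times", t = 1..k;
4. refit each subset on every fold's training split and average held-out
   RMSE (on the transformed scale); the subset with the lowest mean wins,
   ties going to the larger t (sparser model).

During step 2 the intercepts and variance components estimated on the
fold's full feature set are held fixed and only the forest is refitted
per elimination step. The intercept structure belongs to the countries,
not to the candidate subset; refitting it at every step roughly triples
the cost without changing the importance ranking. Step 4, which compares
models, refits the full mixed model per subset. Distinct (fold, subset)
fits are cached since neighbouring thresholds often share subsets.

One practical caveat, visible in the unit tests: impurity importance from
small forests (a few dozen trees) is noisy and biased toward continuous
covariates, so aggressive cuts on tiny feature sets can evict genuinely
predictive binary answers. Elimination-based selection should be run with
at least ~100 trees.

## Farm similarity, user classes, prototypes

The final model's proximity matrix P is converted to dissimilarities
D = 1 − P and embedded by classical metric MDS (principal coordinates:
double-centre −D²/2, eigendecompose, keep the top three coordinates;
non-positive eigenvalues contribute zeros). Farms are labelled High/Low
users by min-max normalising the real and the predicted transformed usage
separately and cutting at 0.5 — a deliberately simple, scale-invariant
split of each vector's observed range, not a calibrated threshold.

k-means (25 restarts) is run on the 3-D embedding for k = 2..10 and the
number of clusters is chosen by BIC, reading the k-means solution as a
spherical equal-variance Gaussian mixture: pooled variance
SSE/(d·(n−k)), parameter count (k−1) + k·d + 1, lower BIC better.
Clustering operates on the embedding rather than the raw n×n
dissimilarity so that what is clustered is exactly what is displayed.

Each (cluster, predicted class) cell is summarised by a prototype: median
for numeric fields, modal level with its frequency for binary answers
(ties broken toward "measure applied" and logged). A class absent from a
cluster yields an explicit not-applicable prototype.

## Effect sizes, strengths and weaknesses

The effect of a binary measure is its partial-dependence contrast: mean
prediction with the answer forced to 1 on every farm minus the mean with
it forced to 0, all other columns untouched. This equals the average
effect of a one-unit change while marginalising over the other variables,
and is checked in the tests against a per-row counterfactual brute force.
Country intercepts cancel in the contrast.

Before effects are computed, remaining "missing" levels are imputed to
0/1 by chained equations with random-forest classifiers (single
imputation, 5 sweeps, mode initialisation, seeded).

Uncertainty: a nonparametric farm-level bootstrap, resampling farms with
replacement *within* country (so every country stays represented and the
intercepts estimable), refitting the whole model, recomputing the
contrast; percentile interval at 95% with 1000 replicates by default
(tests and the shipped studies use 100).

A farm's answers are then crossed with the effect signs: applied +
negative effect, or not-applied + positive effect, is a *strength*; the
complementary cells are *weaknesses* — the candidate action points. Each
weakness must also match an expected biological direction (an editable
YAML: protective / risky / unclear). A measure whose estimated sign
contradicts its mechanism — e.g. a vaccination protocol apparently
raising usage, the signature of reverse causality in cross-sectional data
— stays in the model as a predictor but is never proposed as an
intervention; "unclear" measures are likewise never proposed. None of
this establishes causality; the screens only remove measures with
positive evidence of a non-causal relationship.

## Scenario planner

Every nonempty subset of the screened weaknesses (2^k − 1 scenarios; a
guard rejects k > 15) is evaluated by flipping those answers on the
farm's row and predicting. Because single-forest effect estimates carry
Monte-Carlo noise, the model is refitted 10 times with seeds
seed+0..seed+9 — same data, different forest randomness, since it is the
estimation noise being averaged, not sampling variation — and only
features whose contrast keeps one sign in all 10 runs may enter
scenarios. Each scenario's prediction is back-transformed to TIDDDvet
*before* averaging over the 10 models, so reported values are in usage
units; the averaging order is a documented choice, not a mathematical
identity. Scenarios predicting below the farm's baseline prediction are
kept, the report lists them best-first, and ids are assigned in
descending predicted usage so the deepest reduction carries the largest
index (Scenario_7 of 7 is the full intervention set in the packaged
example).

## Costs

Each measure's yearly cost is linear depreciation of the implementation
cost over its lifetime, plus operational cost, plus an optional scaling
term (per animal: rate × broilers/round × rounds/year; per round; per
stable, with 2 stables assumed when unreported). Scenario cost is the sum
over flipped measures; cost-effectiveness is yearly cost divided by the
predicted TIDDDvet change, hence negative for reductions (euros per unit
of usage removed). The shipped price book
(`amuplan/data/example_costs.yaml`) is synthetic/illustrative — chosen so
the documented worked example's totals (8644.87 €/yr for the full set,
1644.87 €/yr without the depopulation change) hold exactly — and is meant
to be replaced by the user's own prices. Currency is euros on a yearly
basis; no discounting.

## Synthetic data generator

`synthetic.generate_farms` emulates the cross-sectional multi-country
design the analysis assumes: 9 countries × 20 farms by default (a
per-country override allows unbalanced designs such as one country with
21), ~50 independent Bernoulli biosecurity answers with prevalences drawn
once per config from U(0.2, 0.8), log-normal broilers/round centred on a
median of 34 550 birds, integer rounds/year 5–8, log-normal worker counts
centred on 2, a N(0, σ²_country) country intercept, and additive planted
main and interaction effects on the transformed scale with N(0, σ²_noise)
residuals. Defaults: σ_country = 0.5, σ_noise = 0.5, covariate slopes
(−0.3, −0.15, −0.2) on the centred transformed covariates, intercept 4.0
(median usage ≈ 55 TIDDDvet), 3% exact zeros overwritten after
back-transformation, no missingness. Everything is reproducible from the
config seed, byte-identically.

What it does *not* emulate: the correlation structure among real
biosecurity answers (answers are independent given the config), weighted
biosecurity scores, country-specific cost or management structures, and
any nonlinearity beyond the declared interactions. Passing
parameter-recovery tests therefore shows the estimator recovers the
structure it assumes — not that real surveys satisfy those assumptions.

The recovery design used in the tests (`synthetic.recovery_config`)
plants three effects of |0.8| (two harmful, one protective) among 30
answers, with the planted answers fixed at 50% prevalence (maximally
informative, and safely clear of the low-variation filter in every
replicate), σ_country = 1, σ_noise = 0.25, no zeros or missingness. The
coverage design pins its four answers at 50% prevalence for the same
reason.

## Problem sizes of the shipped studies

The simulation studies run on one CPU inside the test suite and the
reproduction script, with sizes chosen accordingly and fixed:

* **RFE recovery** — 20 replicates of the recovery design (180 farms),
  5-fold CV, 100-tree forests, EM capped at 3 iterations (~20 s per
  replicate). Reported: fraction of replicates whose final subset
  contains all three planted features; mean correlation between estimated
  and planted country intercepts; minimum 10-run sign-consistency count
  of the planted features; whether the planner's best scenario flips all
  planted weaknesses.
* **Bootstrap coverage** — 200 replicates of a 48-farm, 4-answer design
  with one planted effect; 95% percentile CIs from 100 within-country
  bootstrap refits of a deliberately small (10-tree) forest; reported
  coverage of 0 for a null feature. Small forests make the per-boot
  effect noisier, which the bootstrap folds into the interval, so
  coverage sits at or slightly above the nominal 95%.
* **Cluster-number recovery** — 40 seeds of two unit-variance Gaussian
  blobs 8 SD apart (120 points, 3-D); reported fraction of seeds where
  BIC selects k = 2.

## Known limitations

* Cross-sectional associations: the expectation screen removes measures
  with evidence *against* a causal reading, it does not certify the rest.
* Zero-usage farms are modelled only through the started-log transform
  and zero inflation in the generator; the fitted model cannot predict an
  exact zero, so plans for already-zero farms only flag risky practices.
  A hurdle-style two-part extension would be the natural refinement.
* Impurity-based importance is biased toward continuous covariates;
  rankings from small forests are noisy (see the RFE caveat above).
* The min-max High/Low user split depends on the observed extremes of
  the sample; it is a descriptive device for the cluster prototypes, not
  a diagnostic threshold.
* The BIC formulation treats k-means clusters as spherical equal-variance
  Gaussians; elongated or unequal-spread clusters can shift the selected
  k.
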