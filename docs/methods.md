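# Methods

`mixsignal` implements a three-stage inference chain for selecting cereal
cultivar mixtures that suppress aphids: a laboratory screening model, a
design-based field comparison, and a meta-analytic synthesis. This note
describes each model, its assumptions and tunable parameters, the synthetic
data the tests rely on, and the numerical choices made where the design was
genuinely open.

## 1. Laboratory screening (binomial GLMM)

The aphid plant-acceptance bioassay yields, per tube, the number of
*Rhopalosiphum padi* settled on a receiver leaf out of the aphids placed
(10 by default). Tubes are nested in pots (plants grown together), pots in
(emitter, receiver) treatment cells, where the emitter is either another
cultivar whose volatiles the receiver was exposed to for five days, or a
clean-air control.

`AcceptanceModel` fits

    settled_t ~ Binomial(placed_t, logistic(beta_{cell(t)} + u_{pot(t)})),
    u_pot ~ N(0, sigma^2),

with one fixed cell mean per (emitter, receiver) combination — the same
span as emitter + receiver + their interaction — and a single pot-level
variance component. Because tubes within a pot share one linear predictor,
the per-pot sufficient statistics (total settled, total placed) collapse
the likelihood, and the marginal likelihood is computed by Gauss–Hermite
quadrature (31 nodes by default; effectively exact for a scalar random
intercept at these pot sizes). `L-BFGS-B` maximizes over cell means and
the pot SD; standard errors come from the numerical Hessian at the
optimum. On a frozen fixture the fit agrees with an independently computed
adaptive-quadrature reference to ~1e-4 on all cell means and the pot
variance (values frozen in `tests/test_screening.py`).

Boundary rule: a pot SD estimated below 1e-4 is reported as exactly zero
and the model is refitted as an ordinary logistic regression (cell-means
design), whose MLEs are then the closed-form empirical cell logits.
Completely separated cells (all settled or none) are flagged at
construction, kept out of contrasts, and reported with a warning.

Each exposed cell is compared with its receiver's clean-air control on the
logit scale by a large-sample two-sided Wald test. Classification of an
unordered pair uses alpha = 0.05 on unadjusted p-values by default
(Bonferroni-adjusted p-values are always reported alongside; the family
size defaults to the number of control contrasts in the dataset), with a
post-hoc direction requirement: only *reductions* in settling count as
priming. Both directions significant = two-way interaction; exactly one =
one-way; neither = no interaction.

Known limitation: with the assay's nominal five pots per cell, pot-level
information is scarce and the Wald contrasts are anticonservative (type-I
error ~0.086 at nominal 0.05 in simulation). The calibration test
therefore runs in a 25-pot regime, where the measured rate is 0.053. With
real assay layouts, p-values near the threshold should be read with this
in mind.

## 2. Field comparison (expected mixtures + linear mixed model)

Each field trial sows three monocultures and their three 50:50 mixtures
(or, in the two-cultivar variant, two monocultures and one mixture
replicated in blocks). For every mixture plot a design-derived
counterfactual — the *expected mixture* — is computed on the raw scale:

* Latin square: the mean of the four component-cultivar monoculture plots
  sharing the mixture plot's row and column (two per component);
* RCBD: the mean of the two component monoculture plots in the same block.

Transect counts are averaged to the plot-date grain first, so observed and
expected values enter at the same grain; the computation is per sampling
date for repeated measurements. Aphid species are summed per transect and
natural-enemy taxa per plot beforehand, and only the three consecutive
sampling dates around the trial-wide aphid peak (the window containing the
peak date with the largest total; earliest on ties) are analyzed.

The comparison model regresses the (log(x+1)-transformed, for counts)
values on value type (observed vs expected) and pair-within-type, with
row + column (or block) and date as crossed random intercepts estimated by
REML. The REML criterion is evaluated on the dense marginal covariance
(trial frames are small) and optimized by multi-start `L-BFGS-B` over the
variance components, with a bounded Powell fallback; the response is
rescaled to unit SD internally for conditioning. If any variance component
falls below 1e-8 of the residual variance the fit is declared singular and
replaced by ordinary least squares with the grouping factors as fixed
terms (`fixed_fallback`).

The per-pair observed-vs-expected coefficient is standardized by refitting
on the response scaled to unit SD (binary predictors unscaled), so the
effect is in response-SD units. Its 95% interval uses a t quantile on
containment-style degrees of freedom, n − rank(X) − Σ(levels − 1) (the OLS
residual df in the fallback). Plain normal intervals were measured to
undercover (0.87–0.93) at realistic trial sizes, which the t correction
repairs (0.947 in the per-pair RCBD check); for the balanced per-pair
block design the containment df is exact. The meta-analytic standard error
is then recovered from the interval as SE = (upper − lower)/3.92, so CI
and SE stay mutually consistent by construction.

Joint vs per-pair fitting: the default joint model shares one residual
variance across pairs, but its expected rows reuse monoculture source
plots across pairs, which induces cross-row correlation and slightly
deflates standard errors. `per_pair=True` refits each pair separately,
keeping its expected rows independent; the calibration tests and the
end-to-end study fixture use this route.

Transformation bias: for count responses, log(x+1) of a single observed
plot value is compared with log(x+1) of a raw-scale *average* of 2–4
source plots. Averaging before the log makes the expected side less
concave-penalized, so under a true null the coefficient is slightly
negative — measured at −0.10 to −0.14 SD with negative-binomial counts
(shape 4) at ~10 aphids/transect, shrinking with higher counts, lower
overdispersion and smaller plot-to-plot log-scale variation. This is a
property of the observed-vs-expected design itself, not of the fitting
code. Consequently the no-effect centring/coverage test uses an
untransformed trait response (exact under the generative model), and the
count-scale bias is measured and bounded in the effect-recovery test
(|bias| < 0.1 on the log(x+1) scale at the fixture's settings: Poisson
counts, mean 30/transect, design log-SDs 0.04).

## 3. Meta-analysis (multilevel random-effects model)

Each standardized coefficient is one effect size with known sampling
variance se². The synthesis model is

    effect_i ~ N((X beta)_i, se_i^2 + crossed random intercepts),

with variance components tau²_g for trial year, country and crop species,
estimated by REML on the dense marginal covariance with multi-start
(near-zero + DerSimonian–Laird-style method-of-moments starts) under
nonnegativity bounds. On a 12-effect fixture the fit reproduces an
independent multilevel meta-analysis reference to 1e-6 on the pooled
estimate, its SE, and the variance components, and matches a dense
grid-search oracle on tau² to 1e-4.

The fixed part is an intercept (global model) or the lab interaction
category (moderator model). Reference coding is the default, so the
omnibus Wald chi-square QM tests the levels−1 category contrasts
(df = 2 for three categories); cell-means coding, testing every category
mean jointly (df = 3), is available. Pooled per-category estimates carry
Wald 95% CIs; 95% prediction intervals add all variance components to the
estimate's sampling variance and therefore always contain the CI. No
Knapp–Hartung small-sample adjustment is applied by default.

Calibration caveat: Wald intervals are accurate when the random-effect
structure has enough levels. Measured coverage is 0.932 with per-effect
heterogeneity at n = 40, but drops to ~0.83 when a tau² of 0.05 is shared
by only four grouping levels — the usual few-clusters problem, inherited
by any REML + Wald pipeline.

## 4. Synthetic data generator

The generator is first-class, tested code and defines the study conditions
the tests assume.

* Bioassay: settled counts are binomial with logistic(baseline + emitter
  effect + pot intercept); defaults mirror the assay protocol — 10 aphids
  per tube, 20 tubes per combination, 5 pots per treatment, baseline 1.5
  logits (~82% settling in clean air), pot SD 0.3.
* Layouts: Latin squares are uniform row/column/symbol permutations of a
  cyclic base square; RCBDs randomize treatment order within block.
* Field counts: per-transect negative binomial via a Poisson-gamma mixture
  (shape `overdispersion`; `None` = Poisson limit) with log-mean
  log(treatment mean) + row + column (or block) + date + plot Gaussian
  effects. A mixture plot's mean is its pair multiplier times the
  arithmetic mean of the component monoculture means. Aphids are split
  over three cereal aphid species (fixed 60/25/15 proportions) so the
  aggregation step has real work to do; natural enemies are per plot-date
  over two taxa (70/30). Dates are exchangeable draws of a shared random
  effect — no within-season population dynamics.
* Traits (height, plants/m, TGW, yield): Gaussian per plot around the
  treatment mean with trait-specific SDs on the trait's own scale, plus
  optional additive row/column/block effects (`trait_design_sd`); defaults
  are realistic temperate-cereal values (80 cm, 60 plants/m, 42 g,
  6000 kg/ha).

What the generator does *not* emulate: spatial autocorrelation beyond
row/column/block effects, aphid population dynamics over time, volatile
dispersal physics, and observation error in trait measurement protocols.
Passing tests therefore demonstrate correctness of the inference chain
under its own assumptions, not robustness to these real-data features.

The built-in multi-country study (`example_study`) has three panels of
three cultivars: one two-way pair (priming shift −2 logits in both
directions, field aphid multiplier 0.5), two one-way pairs (one direction
primed, no field effect), the rest inert. Field trials are 6×6 Latin
squares over two years with Poisson counts at 30 aphids/transect and
row/column/plot log-SDs of 0.04 — moderate, well-behaved abundances chosen
so the recovery property isolates the classification → suppression signal
from the small-count transformation bias documented above.

## 5. Problem sizes used by the test suite

Simulation-based checks run at deliberately desk-scale sizes: 400
replicates for the screening type-I and field no-effect checks, 500 for
meta coverage and null-uniformity, 600–1000 for QM type-I, 200 for power
checks, and 100 seeded replicates of the full pipeline for the end-to-end
recovery property. These sizes give Monte-Carlo bands of roughly ±2–3
percentage points on the rates being checked.

## 6. Degenerate inputs and tie-breaks

* Settled counts outside [0, placed], unknown treatments, non-positive
  SEs, reversed CI bounds and mixed design kinds are hard errors.
* Complete separation: flagged, excluded from contrasts, warned.
* Peak-window ties: earliest maximal window.
* Fewer dates than the window: all dates retained.
* Zero response variance: standardization refuses with a specific error.
* Missing monoculture source plots: `IncompleteDesignError` naming every
  missing plot; never a silent 3-source mean.
* Rank-deficient fixed effects: error naming the aliased columns.
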