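# Methods

## The model

`glmqc` fits generalized linear models in which the modeler can impose
*qualitative* constraints — a sign and/or a monotone shape — on the effect
of each discretized or ordinal covariate and on selected two-way
interactions:

    g(E(y | X)) = α + Σ_j X_j β_j + Σ_{(j,k)∈χ} (X_j · X_k) γ_jk

with the identity link for Gaussian outcomes and the logit link for binary
outcomes.  Continuous covariates enter either linearly (optionally through
a named transform such as `min(x, c)`) or as step functions over declared
bins; nothing is assumed smooth.  The constraints express domain knowledge
of the kind "disease risk rises with age" or "physical activity is
protective with a monotone dose response" and act as a regularizer: they
shrink the feasible set instead of shrinking coefficients.

## Constraint coding by reparameterization

A monotone constraint on a K-level effect curve is converted into pure
per-coefficient sign bounds by incremental (cumulative step) coding: the
working coefficient ζ_k is the increment of the curve at step k, the coded
column indicates that an observation has crossed that step, and the
original dummy-style coefficients are recovered as β = A ζ with a
unit-triangular coding matrix A (lower-triangular of ones when steps
accumulate from the first level, upper-triangular from the last).  The six
meaningful monotone cases and their codings:

| case | monotonicity | sign         | reference end | step bounds      |
|------|--------------|--------------|---------------|------------------|
| 1    | increasing   | positive     | first         | all ≥ 0          |
| 2    | increasing   | negative     | last          | all ≤ 0          |
| 3    | decreasing   | positive     | last          | all ≥ 0          |
| 4    | decreasing   | negative     | first         | all ≤ 0          |
| 5    | increasing   | unrestricted | first         | ≥ 0 for k > 1    |
| 6    | decreasing   | unrestricted | first         | ≤ 0 for k > 1    |

The reference end is forced by the case: an effect curve anchored at zero
on its reference level and monotone away from it necessarily has a
determined sign, so "monotone with unrestricted sign" is only meaningful if
the anchor step is free.  Cases 5/6 therefore leave the first step
unconstrained: the curve is guaranteed monotone over levels 2..K and its
overall sign floats.  Sign-only constraints (no shape) use ordinary
one-hot-minus-reference dummies with a shared bound, anchored at the
user-declared reference level.

Two-way interactions use the Kronecker coding A_j ⊗ A_k of the two
per-variable coding matrices.  For monotone interaction cases the working
coefficients are then exactly the *double increments* of the interaction
surface, so an all-`≥ 0` (or `≤ 0`) bound constrains the surface to be
supermodular (submodular) — e.g. "the protective activity effect becomes
strictly more negative with age".  Monotone interactions require a declared
sign (cases 5/6 are main-effect-only); sign-only and unconstrained
interactions use products of dummy blocks.  With a linear variable on one
axis the block is the raw column and its axis coding matrix is the 1×1
identity.

Design choices worth stating:

* **Discretization** uses half-open bins `[lo, hi)` with the last bin
  closed; values outside the outer edges are clamped into the end bins with
  a warning.  This is robust to survey outliers and is tested as a stated
  convention, not inferred.
* **Reparameterization exactness**: A is unit-triangular, so β ↔ ζ
  round-trips at machine precision, including Kronecker blocks.

## Solver

The reparametrized problem is

    minimize  −ℓ(α, ζ) + (ε/2)·‖ζ‖²   subject to per-column sign bounds,

solved by cyclic coordinate descent on the IRLS quadratic approximation
(for Gaussian outcomes the problem is a single quadratic).  Each coordinate
update is a closed-form minimizer clipped at its bound, so bound
satisfaction is exact — boundary coefficients are exactly zero.  Numerical
choices:

* `ridge_epsilon = 1e-8` by default: effectively unpenalized; the ridge
  term only conditions collinear blocks.  The constraints, not shrinkage,
  are the intended regularizer.  The penalty is defined on the
  original-scale working coefficients so it is invariant to standardization.
* **Standardization** divides columns by their (positive) standard
  deviation; positive scaling preserves sign bounds, and recovered
  coefficients agree with the unstandardized fit to 1e-6 (tested).
* **Convergence**: relative deviance change below `tol = 1e-9`; inner CD
  sweeps run to a much tighter coordinate-change tolerance so the fit
  matches a generic box-constrained optimizer to 1e-6 in objective value
  on small instances (tested against L-BFGS-B, with KKT checks).
* **Degeneracies**: constant columns are dropped with a warning; suspected
  perfect separation (|linear predictor| > 15 on the standardized scale)
  warns and reports the deviance trace; non-convergence returns the fit
  flagged `converged=False` rather than raising.
* The solver path contains no randomness.

## Treatment effects and the ensemble

The treatment is a one-level increase of an ordinal exposure, capped at
the top level; capped individuals have τ ≡ 0.  The S-learner estimate is

    τ̂_i = g⁻¹(η̂_i at w = w_obs+1) − g⁻¹(η̂_i at w = w_obs),

all other covariates fixed.  For the logit link the difference of the two
linear predictors is the individual's log odds ratio, which puts black-box
components and the constrained model's treatment coefficients on one scale.

Two independently fitted components a and b are combined by consensus:
with avg = (τ̂_a+τ̂_b)/2 and σ̂ = |τ̂_a−τ̂_b|/2, the ensemble returns 0
wherever |avg| ≤ q·σ̂ and avg otherwise; q defaults to √2.  Only the
two-component rule is on the tested path.  Component outcome probabilities
at a requested treatment level come either from posterior draws (mean over
draws) or from a constant-effect extrapolation
`p̂|w = ŷ_obs − (w − w_obs)·τ̂`.  The minus sign is deliberate and is the
package default; because the conventional first-order extrapolation would
add the effect, the sign is exposed as `extrapolation_sign` and all tests
derive expectations from the configured formula.  Probabilities are clipped
to [1e-6, 1−1e-6] before odds ratios, and capped individuals are excluded
from lnOR before any averaging.

## The additive surrogate (explanation)

Per-individual lnOR̂ (or τ̂) is explained with a generalized additive model
with pairwise interactions: piecewise-constant shape functions over binned
features (categorical levels as-is; continuous features in 16 quantile
bins), fitted by cyclic boosting of per-bin residual means
(`rounds = 500`, `learning_rate = 0.1`), then `n_pairs = 5` pairwise grids
added greedily by residual-variance reduction.  Shapes are mean-centered
over the training population, importances are population means of absolute
contributions, and fidelity is in-sample R².  The defaults are ordinary
GA²M-style values; nothing in the methodology is sensitive to them, since
the surrogate's deliverable is the importance *ranking* and the monotone
direction of each shape (Spearman sign over bins), which feed the list of
candidate treatment-interaction terms.

## Targeting

Individuals are ranked by estimated benefit per unit cost (benefit = the
estimated outcome *reduction*, −τ̂, summed over outcomes with nonnegative
weights) and selected until the budget — a fraction of total cost — is
exhausted.  Conventions: stable sort (ties broken by input order); the last
candidate must be fully affordable; individuals with negative estimated
benefit remain eligible while budget remains (the optional
benefit-below-cost stopping rule only makes sense when benefits and costs
share a unit and is off by default); capped individuals participate with
zero benefit rather than being excluded from the budget base.  Evaluation
reports the captured fraction of total true benefit, the full
benefit-capture curve, a perfect (truth-ranked) baseline — which dominates
every score vector exactly, not just in expectation — and a seeded random
baseline, which captures fraction f of the benefit at budget f under unit
costs in expectation.

## The synthetic population generator

The generator emulates the structure of an individual-level health survey:

* **Covariates**: age (truncated normal, 18–89), gender, BMI (normal with
  an age drift controlled by `age_bmi_corr`), smoking (30%), secondhand
  smoke (25%), alcohol, fruit/vegetable intake, number of trusted people,
  education years, an income index, and region.  Apart from the age→BMI
  drift, covariates are independent — tests need controllable structure,
  not demographic realism.
* **Treatment**: a 4-level activity variable assigned by a
  proportional-odds logit on a standardized "healthiness" score (younger,
  leaner, non-smoking, higher-income individuals exercise more), with
  strength `confounding` (default 0.5).  Cut points are calibrated by
  bisection so the marginals hit (18%, 45%, 10%, 27%) regardless of the
  confounding strength.
* **Outcomes**: two binary diseases drawn from known logistic structural
  models whose main-effect curves and activity×age / activity×smoking
  interaction surfaces satisfy their own declared constraints (checked at
  construction).  Magnitudes are invented; the qualitative pattern (risk
  rises with age, BMI, smoking; activity protective, more so for older
  individuals and smokers) mirrors the standard epidemiology.
* **Ground truth**: exact per-individual τ and lnOR at every treatment
  level, computed from the structural model — the oracle for recovery and
  targeting tests.

What the generator does *not* emulate: realistic joint covariate
distributions, survey weights, measurement error, item nonresponse, or
multi-wave structure.  Passing tests therefore demonstrate the
methodology's internal correctness and its behavior under known
confounding, not performance on any real survey.

## Problem sizes and observed behavior

The test suite exercises populations of 2,000–100,000 individuals; the
recovery study fits the correctly specified constrained model at
n ∈ {5k, 20k, 50k, 80k}.  Recovered per-term curve error (sup-norm, link
scale) is dominated by the sparsest cells — the 10% activity level crossed
with the oldest age bin at single-digit disease prevalence — and shrinks at
the expected 1/√n rate, while the individual-effect estimates correlate
with the exact truth above 0.98 at n = 50k.  The small-sample
regularization benefit of the constraints is checked at n = 2,000 over 20
replicates: the constrained fit's captured benefit at a 25% budget is at
least that of its unconstrained twin on average.

## Known limitations

* Only two-way interactions; no three-way terms (a documented gap relative
  to fully specifying, e.g., smoking×gender×age).
* Monotone interactions constrain the double increment, which is one of
  several defensible formalizations of "the interaction is monotone".
* No uncertainty intervals on τ̂; no cross-validated penalty path.
* The surrogate explainer is in-sample; its R² is a fidelity measure, not
  generalization.
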