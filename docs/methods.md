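# Methods

## Model and estimands

All estimators assume a logistic disease model

    logit P(Y=1 | A=j, C=c) = μ + β_j + γ(c)          (discrete A)
    logit P(Y=1 | A=j, C=c) = μ + β(j) + γ(c)         (continuous A)

with β anchored at 0 at the reference (minimum-risk) exposure level, no
exposure–confounder interaction on the multiplicative scale, and a rare
disease in every confounder stratum (so conditional odds ratios
approximate risk ratios). Under the standard causal identification
assumptions the counterfactual PAF equals the case-weighted expression

    PAF = Σ_{j≥1} P(A=j|Y=1) (1 − e^{−β_j}),

whose plug-in version `exact_paf_discrete` / `exact_paf_continuous` we
call the *exact* estimator; the *approximate* estimator is the
second-order expansion `PAF_a = P̂ β̂^ave` with `P̂ = P(A≠0|Y=0)` and
`β̂^ave` the control-weighted average log-odds ratio. For continuous
exposures the integrals against the conditional exposure densities
f(j|Y=1) and f(j|Y=0) are replaced by plug-in empirical means over the
observed case and control samples; this is the natural nonparametric
estimator and avoids a bandwidth choice. All log-odds ratios are natural
logs throughout the computation layer; base-10 appears only in nomogram
axis coordinates.

Two deliberate non-clippings: a negative β̂^ave (reference mis-coded as
non-minimum-risk) yields a warning plus the negative result rather than
an error, and `PAF_a > 1` (possible at large odds ratios) is returned
unclipped with a warning. Plot layouts, by contrast, refuse non-positive
inputs, since their log transforms are undefined there.

## Impact fractions

The impact fraction of an intervention lowering control prevalence from
P̂ to P̂′ is implemented as the difference of approximate PAFs,
`(P̂ − P̂′) β̂^ave`. For a halving this coincides numerically with the
approximate PAF evaluated at the halved prevalence; the difference form
is the one that generalizes to arbitrary partial reductions, which is why
it is the definition here.

## Fitting (estimation module)

* Discrete exposures enter the logistic fit as indicator contrasts
  against the declared reference; continuous exposures as a natural cubic
  spline (patsy `cr`, default 4 df, user-overridable). A fixed-df spline
  inside a plain maximum-likelihood logistic fit keeps the estimator
  deterministic; generalized additive alternatives would add a smoothing
  parameter without changing the estimand.
* Coefficients are re-expressed relative to the reference as differences
  of linear predictors (confounders held fixed, so the additive nuisance
  terms cancel exactly); per-level standard errors come from the delta
  method on the coefficient covariance.
* The continuous reference value j0 is the argmin of the fitted log-odds
  curve over a 501-point grid spanning the 1st–99th observed percentiles
  (trimming keeps j0 a realizable value with data nearby); ties break to
  the smallest value, and the curve is re-anchored by subtracting its
  value at j0 rather than re-parameterizing the basis (equivalent, and
  simpler).
* Confounders enter additively: numeric columns linearly, non-numeric as
  indicator contrasts. Rows with missing declared values are dropped at
  load with a logged count.
* Degenerate inputs fail loudly: an exposure level absent among cases or
  controls raises before fitting (naming the level), separation or
  non-convergence raises a fit-failure error with optimizer diagnostics,
  and a control stratum entirely at the reference makes β̂^ave undefined.

## Bootstrap

Confidence intervals are stratified nonparametric percentile bootstrap:
cases and controls are resampled separately with replacement, preserving
both stratum sizes — this respects the outcome-dependent sampling design.
Refits reuse the design matrix built once from the full data (resampling
its rows) and warm-start Newton at the full-data estimate; the estimator
is identical to the full pipeline, just without re-parsing the model
formula 199 times. Failed refits (separation on a resample, a level
dropping out) are skipped and counted, with an error if more than 10%
fail. The resample stream depends only on the seed, so intervals at
different levels from one seed are nested, and runs are reproducible.

## Approximation bias (bias module)

The bias surfaces evaluate, at each (control prevalence p, odds ratio
OR): `PAF_a = p ln OR` and `PAF = π_c (OR−1)/OR`, with the case-side
prevalence obtained by multiplying the control exposure odds by the odds
ratio, `π_c = OR·p/(1−p+OR·p)`. That conversion is exact for a marginal
2×2 odds ratio and consistent with the rare-disease regime in which
conditional and marginal odds ratios coincide; it is isolated in
`case_prevalence_from_control` so a different convention can be swapped
in. `B_r = PAF_a/PAF` is set to 1 at OR = 1 by continuity (both PAFs
vanish there) so surfaces render without holes. Default display grids:
prevalence 0.05–0.95 step 0.01, OR 1.05–5.0 step 0.05. Headline
behaviour, all recomputed by the tests: max |B_r − 1| ≈ 0.176 at OR 1.5
over p ∈ [0.05, 0.90]; under-estimation below p ≈ 0.5 and
over-estimation above; best accuracy near p = 0.5.

## Plot layouts (visualization module)

Layouts are computed in abstract coordinates, exportable as JSON, and
rendered separately — the geometry is unit-testable without a graphics
backend, and SVG output is byte-deterministic (fixed hash salt, no
timestamps).

* Fan plot: factor i at (1/P̂_i, β̂_i^ave); the origin line through it has
  slope P̂_i β̂_i^ave, which is also its intercept on the vertical axis at
  1/P̂ = 1. Ranks are descending in approximate PAF. The x axis is
  labelled in prevalence units by default (decreasing left to right);
  1/P̂ labelling is available. Multicategory factors use P̂(A≠0|Y=0);
  continuous factors have P̂ = 1 and sit on the left boundary.
* Nomogram: three vertical axes at x = 0, ½, 1. With prevalence on the
  left the ordinates are (−log₁₀P̂, ½·log₁₀β̂^ave, log₁₀PAF_a); the OR-left
  ordering swaps the roles. Since log₁₀PAF_a = log₁₀P̂ + log₁₀β̂^ave, the
  middle ordinate is exactly the mean of the outer two, so the three
  points are collinear by construction (any log base works; 10 gives
  readable ticks; axis spacing follows the standard Fagan construction).
  Tick sets: prevalence {1,2,5,…,90}%, OR {1.1,1.2,1.5,2,3,5}, PAF
  {1,2,5,…,100}%.
* Tilts pivot a factor's line about its left-axis point with the middle
  and right values recomputed at a new prevalence. They are only offered
  in the OR-left ordering: with prevalence on the left the pivot itself
  would move, so the construction is ill-posed there. A tilt to lower
  prevalence is styled as an intervention (red dashed; its right-axis
  value is the approximate impact fraction), to higher prevalence as an
  alternative population (blue dashed).

## Synthetic data

The generator draws a confounder (binary or standard normal), an exposure
given the confounder (binary via a logit shift, multicategory via odds
multiplication of the non-reference levels, continuous via a mean shift),
and then potential outcomes from the logistic model at every discrete
level — for continuous exposures at the reference value only, which is
all the PAF needs — using a single shared uniform per subject. The shared
uniform couples counterfactuals monotonically and makes consistency
(Y = Y^a at the subject's own exposure) an identity. The true PAF is then
a Monte-Carlo mean of the counterfactual definition. Named substreams
(confounder / exposure / outcome / sampling) are spawned from one root
seed so adding a stage never perturbs earlier draws.

Default generating model: binary exposure, baseline prevalence 0.3, odds
ratio 1.5 (β = ln 1.5 ≈ 0.405), baseline disease log-odds logit(0.01)
(rare disease, overall prevalence ≈ 1.7% once confounding is included),
and one balanced binary confounder shifting exposure log-odds by 0.4 and
outcome log-odds by 0.7 — a moderate-confounding, approximation-friendly
regime: large enough effects to make unadjusted fits visibly biased,
small enough that the logistic approximations are in their stated domain
of validity.

What the generator does **not** emulate: effect modification (excluded by
assumption), matched designs, measurement error, missingness mechanisms,
and the correlated multi-exposure structure of real risk-factor panels.
Passing tests therefore demonstrate correctness of the estimators under
the assumed model, not robustness to its violations.

## Problem sizes in the test suite

Stochastic end-to-end checks use: a truth oracle of 2,000,000 subjects
(MC SE ≈ 0.002 on the PAF); 20 replicate case-control studies of
5,000/5,000 drawn from 400,000-subject cohorts for approximate-PAF
recovery, with the 3-SE comparison band computed on the difference
between the estimate (delta-method SE) and the MC truth, floored at
0.03; and 200 replicate studies of 500/500 with 199 bootstrap resamples
each for 95%-interval coverage, checked against [0.90, 0.99] (the
binomial tolerance at 200 replicates). Coverage of a percentile bootstrap
is asymptotically invariant to the per-study sample size, so the smaller
replicates measure the same property at a fraction of the cost.

## Known limitations

* Approximation validity is bounded: beyond OR ≈ 3, or prevalence > 0.6
  at moderate ORs, `PAF_a` can be badly off and even exceed 1; the bias
  module exists to make this visible, and plots do not clip it.
* The exact estimator is itself an approximation under non-rare disease
  (odds ratios then overstate risk ratios) and inherits noncollapsibility
  of the odds ratio under confounding.
* Matched/conditional logistic designs, survey weights, effect
  modification, and exact impact fractions under arbitrary joint
  interventions are out of scope.
* Tertile-grouped factors in the bundled summary table carry only their
  published aggregate β̂^ave; per-tertile coefficients are not recoverable
  from the summary inputs.
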