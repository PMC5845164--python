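# Methods

## Estimands

Let T be the time to the first event, J ∈ {1, …, m} its type, X ∈ {0, 1} a
binary exposure, and Z baseline covariates.  Follow-up is right-censored
(code 0).  The package computes, per exposure group and as a contrast:

1. **Restricted mean survival time.**  A(t\*) = E[min(T, t\*)] = ∫₀^t\* S(t) dt
   with S the all-cause survival function.  S is estimated by the weighted
   Kaplan–Meier product-limit curve; because the estimate is a step
   function, the integral is an exact Riemann sum
   Σ_k Ŝ(t_{k−1})(t_k − t_{k−1}) over the ordered event times in (0, t\*],
   with t\* always appended as the final knot.  The horizon must not exceed
   the last observed follow-up time: restriction exists precisely to avoid
   extrapolating the curve.

2. **Cumulative incidence under competing risks.**  For event type j,
   F̂ⱼ(t) = Σ_{t_k ≤ t} Ŝ(t_{k−1}) · dⱼ(t_k)/n(t_k), where dⱼ and n are
   *weighted* event and at-risk totals and dⱼ/n is the discrete
   cause-specific hazard.  Two forms of the overall survival Ŝ are
   available:
   - `product_limit` (default): Ŝ = Π(1 − d/n).  With this form
     F̂ⱼ + F̂_comp + Ŝ = 1 holds *exactly* at every knot (the estimator is
     then the weighted Aalen–Johansen estimator).
   - `exp_cumhaz`: Ŝ = exp(−Σ d/n), the Breslow-type exponentiated
     cumulative hazard.  Since 1 − h < e^{−h} for h > 0, this form makes
     the same sum strictly exceed 1 whenever events have occurred.  The
     discrepancy is O(Σ h²) and negligible when risk sets are large, but
     the product-limit form is the default exactly because the additivity
     identity is structural, not approximate.

3. **Restricted mean time free of all events.**
   A_{J=j}(t\*) − L_{J≠j}(t\*), with A_{J=j} = ∫(1 − F̂ⱼ) the expected time
   to event j (competing events notwithstanding) and L_{J≠j} = ∫ F̂_comp the
   expected time already spent in a competing-event state.  Algebraically
   this equals ∫(1 − F̂ⱼ − F̂_comp), i.e. the area under the all-cause
   event-free curve; in product-limit mode the package satisfies this
   identity to machine precision (it is a standing property test).  The
   decomposition is still worth exposing because its two pieces are the
   interpretable areas between curves (time before the event of interest;
   time lost to competing events).

4. **Comparators.**  Pointwise discrete-hazard ratio curves (all-cause,
   cause-specific, and subdistribution — the latter uses
   ΔF̂ⱼ(t_k)/(1 − F̂ⱼ(t_k⁻)), the hazard whose risk set effectively retains
   subjects after competing events), risk-ratio and risk-difference curves
   from the weighted survival curves, and a weighted Cox partial-likelihood
   estimate for the single exposure coefficient (Breslow tie handling,
   Newton iterations to gradient tolerance 1e−8, divergence beyond
   |log HR| > 15 reported as monotone likelihood).  Points where a ratio is
   undefined (zero reference hazard, empty risk set, no risk accrued) are
   carried as NaN with a defined-flag, never interpolated.

## Weights

Stabilized inverse-probability-of-exposure weights
Ŵᵢ = P̂(X=xᵢ)/P̂(X=xᵢ|Zᵢ): numerator the sample proportion of the subject's
own exposure level, denominator a logistic regression (statsmodels GLM,
binomial family).  Continuous covariates enter via a natural cubic spline
basis (patsy `cr`), default 4 df with interior knots at equally spaced
quantiles — configurable per covariate, since spline flexibility is a
modelling choice the data owner should control.  Categorical covariates are
dummy-coded against a configurable reference level.

Properties used as tests: with no covariates every weight is exactly 1;
under a saturated discrete model the fitted denominators equal stratum
proportions; the mean stabilized weight is ≈1; weighted group covariate
means converge to pooled means (balance).

Guards: fitted probabilities are clipped at [1e−6, 1−1e−6] purely against
overflow; probabilities outside [0.01, 0.99] trigger a logged warning —
positivity is an identification assumption, not something the software can
fix.  Separation (non-finite or exploding coefficients) raises.  Optional
winsorization of weights at inverse-ECDF percentiles is provided as a
robustness utility; it is off by default since the primary analysis uses
untruncated weights.

## Bootstrap

Percentile intervals from subject-level resampling with replacement
(unstratified), with the *entire* pipeline — weight fitting, curves,
integration — re-run per replicate, so weight-estimation uncertainty is
inside the interval.  Quantiles are linear-interpolation empirical
percentiles (immaterial at 10⁴ replicates; fixed for reproducibility).
Replicates that fail (e.g. separation in a small resample) are dropped and
counted; >5% failures aborts.  Each replicate uses its own
`SeedSequence`-spawned generator, making results bit-identical for a seed
and invariant to the worker count used for parallel execution.

## Synthetic cohorts

The generator mimics the structure of an urban HIV clinical cohort at
enrollment: age ~ N(39.5, 8²) years, CD4 ~ Gamma(1.5, 220) cells/µL, log10
RNA ~ N(4.6, 1²), 65% male, race 77/20/3% black/white/other, 22% prior
AIDS, 26% prior ART; a binary exposure from a logistic model on
standardized covariates (intercept calibrated to ≈38% prevalence);
conditionally independent cause-specific event times, (piecewise-)
exponential given exposure and covariates (latent-failure-time
construction), default constant rates 0.30/yr for the event of interest
and 0.12/yr for the composite competing event; administrative censoring at
5 years plus a small (0.02/yr) random censoring rate.  Piecewise-constant
baselines allow non-proportional hazards (e.g. curves that only diverge
after a delay).

Because the mechanism is known, `true_marginal_contrast` computes the true
marginal restricted-mean contrast exactly: conditional on covariates the
event-free survival is piecewise exponential with closed-form integral,
averaged over fresh covariate draws under each counterfactual exposure.
The exposure-assignment model does not enter the truth — confounding
affects who is exposed, not counterfactual outcomes — and this invariance
is itself a test.

`confounded_config` is the standard bias-recovery scenario: covariates push
exposure and hazards in concordant directions so the crude contrast is
biased by ≈0.3 years (several times its sampling SD at n=10,000, which is
≈0.03 years for crude and weighted alike), while the correctly specified
weight model removes essentially all of it.  Exposure-model coefficients
are deliberately moderate so weights stay in single digits and the
effective sample size stays near 85% — extreme weights would inflate the
variance without making the scenario more informative.

What the generator does *not* emulate: staggered calendar entry (the
optional era label is independent structure for exercising stratified
workflows), informative censoring, covariate measurement error, and
time-varying exposure.  Passing recovery tests therefore show correctness
of the estimator under its stated assumptions, not robustness to their
violation.

## Numerical choices and conventions

- Ties: at a tied time, events are removed from the risk set before
  censorings (subjects censored at t are still at risk at t).
- Weighted totals are sums of weights, never rounded; curves are
  right-continuous; Riemann sums evaluate the left limit Ŝ(t_{k−1}).
- Summation-order roundoff can leave a terminal discrete hazard a few ulp
  above 1 when an entire risk set fails at once; hazards are clamped at 1
  with a hard error only beyond 1 + 1e−9.
- Ratio contrasts with a near-zero denominator raise rather than return
  infinities.
- Era-stratified analyses refit weights within each stratum, standardizing
  every stratum to its own covariate distribution (the conservative
  reading when effect modification by era is the question); this is a
  per-call choice, not a global switch.

## Problem sizes used in the shipped checks

Oracle-equivalence and identity sweeps use 1,000 random weighted cohorts of
n ≤ 20 with heavy ties (exact agreement to 1e−12); the closed-form
exponential limit uses n = 100,000; confounding recovery uses n = 10,000
against a 400,000-draw truth; bootstrap calibration uses 500 cohorts of
n = 300 with 200 replicates each, sizes at which percentile intervals are
known to be near-nominal while the whole study stays desk-scale.

## Limitations

- Inference is bootstrap-only; no closed-form (Greenwood/influence)
  variances.
- No censoring weights: censoring is assumed independent given exposure
  (administrative censoring satisfies this by design).
- No left truncation, interval censoring, or time-varying
  exposures/weights.
- Subdistribution hazards are reported as pointwise curves only; no
  subdistribution regression model is fitted.
- The weighted Cox fit handles exactly one binary coefficient — it is a
  comparator, not a modelling tool.
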