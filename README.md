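# ipwrmst

Inverse-probability-weighted restricted mean survival time (RMST) for
time-to-event data with confounding and competing risks.

## The problem

In observational cohorts, hazard ratios are hard to interpret (they are
conditional on surviving, and a single number hides non-proportional
hazards), and with competing risks "time to event" is ill-defined for
subjects whose follow-up ends in a competing event first.  A concrete
example: comparing time to antiretroviral-therapy (ART) initiation between
HIV patients who do and do not inject drugs, where death and loss to clinic
preclude ART initiation, and treatment indications (age, CD4 count, viral
load, ...) confound the comparison.

This package estimates *restricted mean* summaries instead:

- **RMST** — the expected event-free time through a horizon t\*,

  A(t\*) = E[min(T, t\*)] = ∫₀^t\* S(t) dt,

  computed as the exact Riemann sum over the steps of a Kaplan–Meier curve
  (t\* is always a knot; nothing is extrapolated past the observed
  follow-up).
- **Weighted curves** — survival and cumulative-incidence curves are
  standardized with stabilized inverse-probability-of-exposure weights
  Ŵᵢ = P̂(X=xᵢ) / P̂(X=xᵢ | Zᵢ), the denominator a logistic model with
  natural-cubic-spline terms for continuous covariates, so both exposure
  groups are marginalized to the pooled covariate distribution.
- **Competing risks** — the weighted cumulative incidence for event type j,

  F̂ⱼ(t) = Σ_{t_k ≤ t} Ŝ(t_{k−1}) · dⱼ(t_k)/n(t_k),

  and the restricted mean time spent *free of all events*,

  A_{J=j}(t\*) − L_{J≠j}(t\*) = ∫(1 − F̂ⱼ) − ∫ F̂_comp,

  e.g. "years spent alive, in clinic, and not yet on ART".
- **Inference** — percentile bootstrap (2.5th/97.5th percentiles of
  subject-level resamples), re-estimating the weights inside every
  replicate.
- **Comparators** — pointwise all-cause / cause-specific / subdistribution
  hazard-ratio curves, risk-ratio and risk-difference curves, and a
  weighted Cox hazard ratio for a binary exposure.
- **Synthetic cohorts** — a generator with confounded exposure and
  cause-specific (piecewise-)exponential event times whose true marginal
  contrast is available in closed form, for calibration and bias studies.

## Worked example

```python
import ipwrmst as iw

cfg = iw.confounded_config(n=10_000, seed=0)      # known ground truth
cohort = iw.generate_cohort(cfg)
coding = iw.EventCoding(event_of_interest=1, competing_codes={2})
spec = iw.CovariateSpec.from_names(
    continuous=["age", "cd4", "log10_rna"],
    categorical=["male", "race", "prior_aids", "prior_art"],
)

weights = iw.fit_stabilized_weights(cohort, spec).weights
from ipwrmst.rmst import group_estimates
e1, e0, diff = group_estimates(cohort, weights, coding, horizon=5.0,
                               estimand="event_free_rmst")
truth = iw.true_marginal_contrast(cfg, "event_free_rmst", 5.0)
print(f"exposed {e1.value:.3f}  unexposed {e0.value:.3f}  "
      f"difference {diff.value:+.3f}  truth {truth:+.3f}")
```

prints

```
exposed 1.958  unexposed 1.920  difference +0.038  truth +0.068
```

that is: exposed subjects spend an estimated 1.96 of the first 5 years free
of both events versus 1.92 for the unexposed — a +0.04-year difference,
close to the simulated truth of +0.07, while the crude (unweighted)
difference on the same cohort is −0.23 years, the wrong sign entirely.

The same analysis is scriptable end-to-end:

```sh
ipwrmst simulate --n 3000 --seed 1 --out cohort.csv
ipwrmst run-all cohort.csv --config analysis.yaml --n-boot 1000 --seed 1 --outdir results/
```

producing weight diagnostics, per-group curve CSVs, an RMST results table
(overall and per enrollment-era stratum, with bootstrap CIs), and
comparison-estimand curves.

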