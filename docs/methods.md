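# Methods

## The model

`burnfluid` models the first 48 hours of fluid resuscitation in severe
thermal burn adults (TBSA ≥ 30%) as three coupled components.

**Protocol arithmetic.** The TMMU protocol prescribes
`1.5 mL × weight(kg) × TBSA(%) + 2000 mL` for the first 24 hours (1 mL
crystalloid + 0.5 mL colloid per kg per %TBSA plus 2 L water) and half the
crystalloid/colloid plus another 2 L water for the second 24 hours. Half
the first-day fluid is scheduled in hours 1–8, the rest uniformly over
hours 9–24, the second-day volume uniformly over hours 25–48. Bedside
titration is rule-based: ±20–30% when hourly UOP leaves 30–60 mL/hr. The
protocol states a range without a selection rule, so the step is a
parameter `step_fraction ∈ [0.20, 0.30]`, default 0.25. The rule is
applied to the total rate (the crystalloid-only alternative is not
distinguishable from the source description). The 2 L daily water follows
the same temporal split as the rest of the fluid; its distribution is not
specified by the protocol. Volumes are continuous mL, rounded only for
display.

**Basic infusion rate.** The cohort-mean hourly rate follows
`Rate(t) = a1·e^(−a2·t)` (amplitude mL/hr, decay 1/hr), fitted by
least squares on the rate scale with a log-linear regression supplying
starting values and a bounded trust-region refinement (`a1 > 0, a2 ≥ 0`).
By default the decay is fitted to the mean rate at each post-burn hour
(`decay_fit="cohort_mean"`); pooled patient-hours are a config option.
Patient-level variation enters through the *adjusting factor* — each
patient's mean rate over their observed hours in 1–48 divided by the
cohort mean — regressed linearly on TBSA: `Adjust = b1 + b2·TBSA`. Body
weight is excluded by default (its correlation with the factor is weak in
a population with narrow weight spread) but can be added with
`include_weight=True`. Patients with fewer than `min_hours=12` observed
hours are excluded from the factor regression. Extrapolated adjusters are
clamped below at `adjuster_floor=0.1` with a logged warning.

Note an intentional scale convention: `a1` and the adjuster intercept are
only jointly identified (a constant can move between them). The factor
construction normalizes the mean factor to exactly 1 over the fitted
cohort, so the product `Base_Rate(t) = Rate(t)·Adjust_TBSA` — the quantity
every downstream component consumes — is what is estimated consistently,
not `a1` and `b1` separately.

**UOP prediction.** The one-step-ahead predictor is

```
UOP_Pred(t+1) = c1·OR(t)·(ΣF − ΣU)/t + c2·IR(t)·Base_Rate(t+1) + Pred_Err(t+1)
Pred_Err(t+1) = d1·(UOP_Pred(t) − UOP(t)) + d2·(UOP(t) − UOP(t−1))
```

with OR the cumulative urine/fluid ratio and IR the hourly ratio.
Predictions start at each patient's third observed hour (two hours of
burn-in); the first prediction has no prior prediction error and uses the
d2 term only. Predictions are floored at 0 mL/hr. Hour gaps split a series
and the burn-in is re-applied. Zero-infusion hours carry the last defined
instant ratio forward (logged); zero cumulative fluid defers prediction.

Two structural readings the source leaves open are configurable:

* `eq_parse` — the long-term term's ratio may be the current overall ratio
  (default `"current"`; the retained fluid per hour scaled by the urine
  conversion rate, the reading consistent with the ratio's physiologic
  role), the previous hour's ratio (`"lagged"`), or the reciprocal
  (`"inverse"`).
* `error_feedback` — which prediction's error feeds the recursion. The
  default `"regression"` feeds back the error of the c-term (regression)
  part. The literal alternative `"full"` (the corrected prediction's
  error) has a degenerate property: on data generated by the model itself
  the full-prediction error is identically the noise term, so with clean
  data `d1` multiplies an exactly-zero regressor and is unidentifiable.
  The regression-part convention keeps all four coefficients identifiable
  from noise-free data and is what the estimator and generator use.

**Estimation.** Pooled across patients (no hierarchy), sequentially:
`(c1, c2)` by zero-intercept least squares of next-hour UOP on the two
ratio terms (an intercept is available for diagnostics), then `(d1, d2)`
by regressing the residuals on the previous prediction error and the UOP
change. Because the feedback regressor is itself a function of the c's,
the plain two-stage estimates are then refined by a joint Gauss–Newton
pass — the full residual is bilinear in `(c, d)` — which on self-generated
clean data reaches the exact zero-residual solution (recovery to ~1e−13 in
the tests). `max_iter=1` keeps the plain two-stage fit. A condition-number
check (> 1e10) rejects collinear regressor sets. Reported standard errors
come from the stage-wise normal equations at the final coefficients and
are approximate (they ignore cross-stage dependence); the `R²`, residual
lag correlation and residual/UOP-change correlation are diagnostics of the
feedback structure.

**Controller.** The prediction is affine in the coming hour's rate with
slope `c2·IR(t)`. In-range predictions retain the basic rate; out-of-range
predictions are driven to the band midpoint (`UOP_target = (lower +
upper)/2`) by inverting the affine map, clamped to
`[rate_min, rate_max]` (defaults 50 mL/hr and twice the basic rate — the
source specifies no clamp; both are configurable, and a clamped decision
is flagged `saturated`). A zero slope (anuric hour or `c2 = 0`) cannot be
inverted; the rule-based ±20–30% protocol step is used instead, logged,
and flagged `fallback`. The inversion is reconstructed from the model's
affine structure rather than transcribed from the source (whose equation
bodies are rendered as figures); a proportional-scaling alternative could
be swapped in behind the same `decide_rate` interface.

**Replay.** `replay_cohort` walks recorded patients hour by hour, always
advancing the state on the *actual* intake and UOP — an offline what-if,
not closed-loop simulation. Following the validation convention, in-range
hours keep the recorded actual rate (`use_actual_when_in_range=True`), so
a replay in which every prediction is in range conserves the recorded
volume exactly; out-of-range hours take the inverted rate. Volumes are
accumulated per 24-hour post-burn block.

**Evaluation.** Absolute error `|pred − actual|` uses every predicted
hour; relative error divides by actual UOP and excludes (but counts)
zero-UOP hours. Over-range detection pools above-band and below-band into
one positive class; sensitivity/specificity are undefined (NaN, flagged)
when a class is empty; accuracy pools both classes. Paired volume
comparisons use the standard paired two-sided t-test; identical pairs give
t = 0, p = 1, and spread-free nonzero differences are flagged degenerate.
Summary SDs use the n−1 denominator. Cohort summaries split block volumes
into crystalloid/colloid/water by each patient's protocol composition
fractions, since hourly records carry only total infusion.

## The synthetic cohort generator

No patient-level data are deposited, so the generator emulates the study
conditions with known ground truth; defaults (all configurable in
`SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| cohort sizes | 13 + 24 | derivation/validation split of the study |
| weight | normal 61.8 ± 9.5 kg, truncated 40–100 | cohort moments |
| TBSA | uniform 30.2–97.0% | reported burn-extent range |
| age | normal 41.7 ± 13.9 y, truncated 16–60 | inclusion criteria |
| decay truth (a1, a2) | 360 mL/hr, 0.0126 /hr | reproduces first/second-day mean rates ≈ 308/228 mL/hr |
| adjuster truth (b1, b2) | 0.492, 0.008 /% | mean factor ≈ 1 at the TBSA midpoint; with factor scatter 0.08 the design TBSA~factor correlation is 0.888 |
| UOP truth (c1, c2, d1, d2) | 0.25, 0.8, 0.4, −0.39 | places the recursion's stable urine/fluid operating ratio at `1 − (1 − c2)/c1 = 0.2`, near the observed overall ratio ≈ 0.22, with a subcritical hourly feedback gain (c2 < 1) so trajectories do not run away; the d-signs match the reported error correlations |
| rate noise | lognormal σ = 0.15 | hour-to-hour titration variability: rates were adjusted by ±20–30% steps whenever UOP left the band, which a smooth curve with a few-percent jitter would badly understate |
| UOP noise | Gaussian σ = 5 mL/hr | plausible hourly measurement/recording error |
| responsiveness | 0.21 initial, +0.002/hr | initial instant ratio at its observed first-day value, drifting upward to emulate the diuretic phase (second-day urine rises while infusion falls) |

Urine is generated from the prediction recursion itself (so the estimator
is well-specified and parameter recovery is a meaningful acceptance
surface), driven by the patient's adjuster-line base rate rather than the
noisy recorded rate — hourly rate fluctuation is treated as
recording/titration noise, which avoids building an errors-in-variables
bias into recovery experiments. Two departures are available on purpose:
`protocol="tmmu_rule_based"` replaces the smooth rate curve with the
protocol schedule plus the ±20–30% rule, and `uop_mechanism="retention"`
is a deliberately misspecified urine mechanism (delayed fluid
mobilization) for robustness probes. An option (`truncate_start`) draws an
admission delay uniform on 0–12 h, mimicking incomplete early records. All
randomness flows from one seed through named substreams; regeneration is
byte-identical.

**What passing tests do and do not show.** The generator targets
statistical structure, not capillary-leak physiology: no inhalation
injury, no escharotomy, no diuretics, no measurement artifacts beyond iid
noise, and a urine mechanism that (by design, except in the retention
mode) matches the fitted model's form. Recovery and accuracy results on
synthetic cohorts therefore validate the estimator, the recursion and the
controller algebra — they do not certify clinical performance on real
patients.

## Numerical choices and problem sizes

* Decay fit: log-linear initialization, `scipy` trust-region least squares
  with `a2 ≥ 0`; a flat series returns `a2 = 0` exactly at the bound.
* Coefficient refinement: Levenberg–Marquardt on the bilinear residual,
  tolerances 1e−12, seeded by the two-stage fit.
* Recovery experiments run 100 cohorts of 13 patients × 48 hours at
  default noise with the diuresis drift off (the well-specified regime in
  which estimator bias is attributable to the estimator); the suite keeps
  these sizes so the full run stays in seconds. One caveat observed in
  development: with weak rate excitation (hourly rate CV of a few percent)
  the feedback coefficients become weakly identified and an AR-like
  spurious least-squares basin can win on occasional realizations;
  realistic titration variability removes the problem.
* Ties/degenerate inputs: in-range titration is idempotent; degenerate
  target bands (lower ≥ upper), zero TBSA variance, zero cohort mean rate,
  non-finite coefficients and inverted model files all raise immediately
  rather than propagating NaNs; undefined ratios defer the prediction for
  that hour and are logged.

## Known limitations

* The controller equations are an algebraic reconstruction (see above);
  the source's literal printed forms are not machine-readable.
* Pooled (not hierarchical) coefficient estimation; patient-level random
  effects beyond the TBSA adjuster are not modelled.
* The error-feedback convention is the regression-part reading; the
  literal full-prediction reading is available but not identifiable from
  clean self-generated data.
* No hemodynamic covariates (heart rate, MAP), no pediatric dosing, no
  alternative resuscitation formulas, and no real-time pump interface:
  this is an offline decision model.
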