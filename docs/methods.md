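# Methods

`twinppd` implements a register-style analysis of postpartum depression
(PPD) risk in parents of twins compared with parents of singletons: cohort
construction with a washout period, a composite first-event outcome, a
piecewise-exponential Poisson hazard model with restricted cubic spline
time effects, and standardized absolute and relative risk estimands. All
stages run on synthetic registries with known ground truth, because the
individual-level register data such analyses use in practice are
confidential.

## Outcome and cohort definitions

A parent-birth enters follow-up on the day of childbirth and is followed
for 365 days. The outcome is the first of a depression diagnosis (ICD-10
F32–F33, Danish-dialect `DF32`/`DF33` prefixes also accepted) or a
redeemed antidepressant prescription (ATC N06A); sensitivity modes use
diagnoses only or prescriptions only. Codes are matched by string prefix
after upper-casing and stripping dots.

Washout: a parent-birth is excluded if the parent has any qualifying event
— either code family, regardless of the outcome mode, since washout
defines *new-onset* depression — in the half-open window
`[birth − 730 d, birth)`. An event on the birth date itself counts as a
postpartum outcome, not washout; follow-up starts at childbirth, so the
boundary must fall on one side and this is the side consistent with
outcome ascertainment "from the date of childbirth". Mothers and fathers
are screened independently and analysed in separate models, never pooled.

Event days are recorded at register (integer-day) resolution; a recorded
day `d` maps to a continuous exit time `d + 0.5` (mid-day convention), so
day-0 events carry positive risk time and the Poisson likelihood stays
well defined. An event recorded on day 365 exactly is kept with exit time
capped at 365.0. Parents with no qualifying event are censored at exactly
365 days.

## Person-period expansion

Each follow-up record is split over half-open 30-day bands
`[0,30), [30,60), …, [330,360)` plus a terminal `[360,365]` band — the
short band is kept rather than merged so the 365-day horizon is preserved
exactly. A record exiting at `t` contributes the full width to every band
closing at or before `t` and `t − band_start` to the band containing `t`;
its event (if any) is assigned to that band. Total risk time and events
are conserved exactly (tested to 1e−9).

Each row carries a time covariate at which the hazard spline is evaluated:
the midpoint of the occupied part of the band (default), which minimizes
within-band approximation bias; evaluation at the band start is available
as a sensitivity flag. Exact-to-event risk time (rather than full-band) is
used in the event band.

## Hazard model

The hazard is modelled as piecewise-constant at person-period resolution
via Poisson regression with a log risk-time offset:

```
events_ij ~ Poisson( risk_days_ij * exp(x_ij' beta) )
```

The unadjusted linear predictor is `intercept + rcs(t) + twin +
twin × rcs(t)`, where `rcs(t)` is a 4-knot restricted cubic spline
(Harrell's normalized truncated-power basis: the time variable plus two
nonlinear columns that vanish below the first knot and are linear beyond
both boundary knots). Any tail-linear basis spanning the same space gives
identical fitted rates; this invariance is tested by refitting under an
affine transformation of the basis. Adjusted specifications add 4-knot
splines in parental age and calendar year, ART treatment, an ART ×
calendar-year spline interaction (the contribution of assisted
reproduction to twinning declined over the period), cohabitation, and —
for mothers — primiparity.

Default knot placement is the Harrell convention (5th/35th/65th/95th
percentiles of observed event times, or of the covariate for the age and
year splines); fixed user-supplied knots are accepted, and all results
should be reported alongside the knots used, since spline results are
sensitive to knot placement.

Fitting is by iteratively reweighted least squares with step-halving:
start values put the intercept at `log(total events / total person-days)`
and everything else at 0; convergence requires a relative log-likelihood
change below 1e−10 (max 100 iterations), followed by one polishing Newton
step so coefficients are accurate to well beyond the stopping rule. A
scale-normalized eigenvalue check raises a named-column error on rank
deficiency. The fit matches `statsmodels` GLM and a derivative-free
likelihood maximization in tests.

Within-parent dependence (parents contributing several births) is handled
by a cluster-robust sandwich covariance `A⁻¹ B A⁻¹`, with `A` the observed
information and `B` the sum of per-cluster score outer products. No
small-sample correction factor is applied: the estimator then reduces
exactly to HC0 under singleton clusters and halves exactly when every
cluster is duplicated, and cluster counts in the intended use are in the
tens of thousands, where the correction is negligible.

## Estimands

* **Standardized rates.** g-computation at a fixed reference covariate
  profile: the linear predictor is evaluated with covariates at the
  profile values, which may be fractional for binary covariates
  (standardization at marginal means). Built-in profiles mirror the
  marginal means of the Danish 1997–2019 parent cohorts (mother: age 30,
  year 2008, cohabitation 0.93, ART 0.05, primiparity 0.44; father: age
  33, year 2007, cohabitation 0.94, ART 0.05).
* **Cumulative incidence.** `risk(t) = 1000·(1 − exp(−Λ(t)))` with `Λ` the
  integral of the standardized rate (composite Simpson on a ≤0.5-day
  grid; accurate to ~1e−8 relative for smooth hazards, exact for constant
  ones). The proper survival transform is used rather than raw `Λ`; at
  2% annual risks the difference is below 0.03 per 1000.
* **HR(t).** `log HR(t) = twin coefficient + interaction coefficients ·
  rcs(t)`; being linear in the coefficients its variance is a quadratic
  form with the cluster-robust covariance, and the CI is Wald on the log
  scale.
* **Landmark cumulative RRs** at days 90/180/270/365 (3/6/9/12 months at
  30-day months, with 12 months pinned to the 365-day horizon):
  `RR(t) = risk_twin(t)/risk_singleton(t)` under a common profile.
* **Intervals** for cumulative incidence and RR come from parametric
  simulation: 10,000 coefficient draws from a multivariate normal at the
  estimates with the cluster-robust covariance, pushed through the risk
  transform, percentile 2.5/97.5. Twin and singleton curves share the
  same draws, so RR intervals propagate the full coefficient correlation;
  a fixed seed makes intervals exactly reproducible. A delta-method
  interval is available for HR(t) by construction.

Crude cumulative risk ratios from case counts and cohort sizes are
provided as a printed-number oracle; they agree with model-smoothed RRs
only approximately at interior landmarks.

## Synthetic registry generator

The generator emulates the structure of the linked Danish registers: a
births table (one row per parent per childbirth with plurality, age,
calendar year, ART, cohabitation, and parity for mothers) and a dated
events table with prefix-matchable ICD-10-like and ATC-like codes.

* Twin fraction 2% (binomial per childbirth).
* Baseline (singleton) hazard on [0, 365]: log-hazard quadratic in time —
  a Gaussian bump peaking at day 60 with width 110 d — normalized so the
  365-day cumulative incidence is 20 per 1000, the order of magnitude of
  register-based PPD incidence. Constant and piecewise-constant shapes
  are available; a `risk_scale` convenience multiplies the 365-day risk
  (×5 in recovery studies, so desk-scale replicates have enough twin
  events for stable estimation).
* Twin effect: a time-varying log hazard ratio. The register-shaped
  default (`SplineLogHR`) is a natural cubic spline (knots 30/105/195/330
  d) pinned to the published mother pattern — peak HR 1.3 at day 60 with
  zero slope, 1.15 at 6 months, 1.05 at 10 months. Because this curve
  lies inside the span of the analysis model's time spline, recovery
  studies fitted with the same knots measure estimation error, not spline
  approximation error; a Gaussian-bump alternative (`BumpLogHR`) outside
  the model span is provided for misspecification experiments, and a
  constant log-HR for proportional-hazards studies.
* Event times are drawn by inverse-transform sampling from the cumulative
  hazard (trapezoid-integrated at 0.25-day steps) and floored to integer
  days, matching register day resolution.
* Pre-birth events are a homogeneous Poisson process (default 1e−4/day,
  giving ~7% washout exclusions) placed uniformly over the 3 years before
  the first birth, so both washout-hit and washout-miss cases occur.
* Clustering: by default ~30% of parent couples contribute a second birth
  730–1825 days after the first with freshly drawn covariates; this
  exists solely to exercise the cluster-robust variance.
* Covariates follow the marginals of the Danish 1997–2019 cohort (mother
  age N(30, 4.5²), father age N(33, 5²), ART 33.6% in twins vs 4.4% in
  singletons, cohabitation 93%, primiparity 44%); they do **not** affect
  the simulated hazard. Adjusted models therefore estimate true null
  covariate effects — the generator exercises their machinery, not
  confounding.

`true_curves` returns the analytic ground truth (cumulative incidence per
1000 and momentary HR) for any scenario, for parameter-recovery tests.

What passing tests on these synthetics do *not* show: robustness to
confounding by covariates, informative censoring, coding error, delayed
registration of diagnoses, or any feature of real register data beyond the
simulated structure. The published adjusted estimates themselves (HR 1.28
at 2 months for mothers, adjusted 12-month cumulative incidences
23.8/20.7/15.7/14.1 per 1000, …) require the confidential individual-level
data and are used only to calibrate the shapes of the synthetic scenarios.

## Numerical choices and conventions

* Same-day diagnosis + prescription ties resolve to diagnosis
  (severity-first).
* Quantiles in descriptive tables use (n+1)-position linear interpolation
  between order statistics (Hyndman–Fan type 6); percentages round
  half-up to one decimal, matching registry-table formatting. Calendar
  periods are 1997–2004 / 2005–2011 / 2012–2019.
* Descriptive denominators: role-specific parent counts for parent
  variables, unique childbirth counts for childbirth variables; missing
  values leave the numerator but stay in the denominator.
* Degenerate inputs are rejected with explicit errors: negative hazards,
  empty scenarios, unparseable dates, unknown roles, zero events, rank
  deficiency (naming the collinear columns), fewer than four distinct
  event times for knot selection, fewer than two clusters.

## Problem sizes in the test suite

Distributional checks run at 100,000–200,000 births (agreement within 3
Monte Carlo SE of closed forms). Parameter recovery uses 100 replicates
of 50,000 births at ×5 risk — mothers' model, ~1,000 twins and ~5,000
events per replicate — for the time-varying-HR, landmark-RR, and
constant-HR coverage studies; null calibration uses 100 replicates of
20,000 births. These sizes give Monte Carlo standard errors a few percent
of the quantities checked while keeping a full run of the suite in the
minutes range.

## Known limitations

* No multi-timescale Lexis splitting (only time since childbirth), no
  penalized splines, no frailty models, no Cox comparison, no missing-data
  imputation — all out of scope by design.
* The generator draws mother and father outcomes independently from the
  same hazard; real couples' risks are correlated.
* Primary/secondary diagnosis position is not modelled; any
  diagnosis-kind event qualifies.
* The washout boundary (whether the window includes the birth date) and
  the within-band spline evaluation point are conventions the underlying
  registry analyses leave unstated; both are configurable and documented
  above.
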