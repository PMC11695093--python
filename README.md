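# twinppd

Postpartum depression (PPD) risk and timing in parents of twins compared
with parents of singletons, as a reusable register-style survival
pipeline. The package is written for epidemiologists and biostatisticians
who analyse administrative health registers: it builds eligible cohorts
from births + events tables, fits a flexible parametric hazard model, and
turns the fit into the estimands such studies report — with a synthetic
registry generator so every stage is testable against known ground truth
(real register extracts of this kind are confidential).

## The model

Follow-up runs from childbirth (day 0) to day 365. Each follow-up record
is split into 30-day person-periods (Lexis expansion), and the hazard is
fitted by Poisson regression with a log risk-time offset — the
piecewise-exponential likelihood:

```
d_ij ~ Poisson( y_ij · exp(x_ij' β) )
```

where `d_ij` and `y_ij` are the events and risk days of record *i* in band
*j*. The linear predictor contains a restricted cubic spline in time since
childbirth (4 knots), a twin indicator, and twin × time-spline
interactions, so the twin effect can vary over the first year; adjusted
specifications add splines in parental age and calendar year, ART
treatment (with an ART × year interaction), cohabitation, and parity for
mothers. Mothers and fathers are always modelled separately, and variance
is cluster-robust at the parent level (parents can contribute several
births).

From a fit the package computes, with 95% confidence intervals:

* standardized cumulative incidence per 1000 at a reference covariate
  profile (g-computation at marginal means; fractional indicator values
  allowed), `risk(t) = 1000·(1 − e^{−Λ(t)})`;
* the momentary hazard-ratio curve
  `HR(t) = exp(β_twin + β_twin×rcs · rcs(t))`;
* landmark cumulative risk ratios `RR(t) = risk_twin(t)/risk_single(t)`
  at 3/6/9/12 months (days 90/180/270/365);
* crude risk ratios from case counts, and registry-style descriptive
  tables.

Intervals for risks and RRs come from 10,000 seeded coefficient draws
propagated through the risk transform; HR(t) intervals are Wald on the
log scale. See `docs/methods.md` for the full account.

## Worked example

`examples/` contains one short script per capability. The core loop
(`examples/03_fit_hazard_model.py` and `examples/04_effect_curves.py`):

```python
import twinppd as tp

scenario = tp.paper_shaped_scenario(n_births=50_000, seed=11, risk_scale=5.0)
cohort   = tp.build_cohort(tp.simulate_scenario(scenario), role="mother")
periods  = tp.split_follow_up(cohort)
spec     = tp.ModelSpec(role="mother")
fit      = tp.fit_piecewise_poisson(periods, spec, tp.default_knots(cohort, spec))
curves   = tp.estimate_curves(fit, profile=None, n_draws=2_000, seed=1)
```

which prints (from the example scripts, seed 11):

```
47181 records -> 572079 person-period rows, 43,880 person-years
knots at days [10.5, 69.5, 131.5, 250.5]
converged in 6 IRLS iterations; 4682 events, 36546 parent clusters
...
joint Wald test of twin x time terms: chi2(3) = 5.11, p = 0.164

twin      365-day risk  133.7 per 1000 (95% CI 115.3-158.7)
singleton 365-day risk   98.4 per 1000 (95% CI 95.8-101.1)

HR at day 60: 1.08 (95% CI 0.75-1.57); true value 1.30

landmark cumulative risk ratios (twin vs singleton):
  day  90: RR 1.37 (95% CI 1.10-1.75); true 1.29
  day 180: RR 1.40 (95% CI 1.19-1.67); true 1.26
  day 270: RR 1.38 (95% CI 1.19-1.64); true 1.23
  day 365: RR 1.36 (95% CI 1.17-1.61); true 1.22
```

Reading this: the generator encodes a twin:singleton hazard ratio peaking
at 1.30 around day 60 and a singleton 365-day risk of 100 per 1000 (20
per 1000 scaled ×5 so a desk-sized run has enough twin events). The
singleton curve is estimated tightly; with only ~2% twin births a single
draw estimates the twin contrast noisily — every interval above covers
its true value — and averaged over replicates the estimates centre on the
truth (that is what the test suite verifies over 100 replicates).

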