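# ivswitch

Timely conversion from intravenous (iv) to oral antibiotics is a core
antimicrobial-stewardship practice: once a patient is clinically stable,
continuing iv therapy adds line-infection risk, nursing workload and cost
without clinical benefit.  `ivswitch` implements an *electronic switch
trigger tool* for hospital pharmacy/laboratory data and the statistical
machinery to evaluate such an intervention:

- **Trigger engine** — a daily scan of active iv antibiotic orders that
  issues a switch reminder when an order has run 48–72 h (and again at
  96–120 h if still on iv), unless one of five exclusion rules fires:
  rising CRP during treatment, neutrophils < 0.5·10⁹/L, leukocytes
  < 1·10⁹/L, no oral intake (parenteral-only medication or TPN), or a
  severe-infection regimen (e.g. a carbapenem, or high-dose flag).  At
  most two reminders per order; none on weekends.
- **Switch review** — categorises each reminder's outcome against four
  clinical switch criteria into *appropriate switch*, *inappropriate
  switch*, *appropriate iv continuation* or *inappropriate iv
  continuation*, and computes adherence = appropriate switches / eligible
  prescriptions.
- **Controlled interrupted time series (ITS)** — monthly outcome series
  (% of iv prescriptions > 72 h; median iv duration) are fitted by
  segmented linear regression

  y_t = β₀ + β₁·t + β₂·post_t + β₃·(t − t_b)·post_t + ε_t

  where post_t indicates periods at or after the intervention start t_b.
  β₁ is the pre-intervention slope, β₂ the change in level (immediate
  impact), and β₁ + β₃ the post-intervention slope; a two-arm joint model
  with full arm interactions yields the intervention-minus-control
  differences with their standard errors.
- **Synthetic ward cohort generator** — a reproducible two-arm, 26-month
  prescribing record (orders, CRP/leukocyte/neutrophil series, intake
  flags) whose monthly P(duration > 72 h) follows a configurable
  segmented trajectory, so the whole pipeline can be exercised end to end
  without patient data.

## Worked example

```python
from ivswitch import (SimConfig, simulate_cohort, monthly_series,
                      ControlledITS, WardGroup)

cohort = simulate_cohort(SimConfig(), seed=1)      # ~12,000 orders, 26 months
points = {arm: monthly_series(cohort.orders, arm, cohort.observation_window)
          for arm in WardGroup}
fit = ControlledITS.from_monthly_points(points, break_index=14).fit()
print(fit.summary())
```

```
Controlled interrupted time-series analysis
== intervention arm ==
Segmented interrupted time-series regression (OLS)
  periods: 26   break at t=14   df_resid: 22   resid var: 25.74
  pre-intervention slope : -0.27 (0.38), p=0.483
  change in level        : -17.81 (4.00), p=0.000
  post-intervention slope: 0.43 (0.38), p=0.262
  change in slope        : 0.70 (0.53), p=0.201
== control arm ==
...
== intervention - control ==
  pre-slope difference   : 0.09 (0.42), p=0.834
  level-change difference: -11.30 (4.51), p=0.016
  post-slope difference  : 0.68 (0.42), p=0.114
```

The generator planted an abrupt −19.3 percentage-point drop in the
intervention arm's % of prescriptions > 72 h at month 14 (and −6.1 in the
control arm); this single replicate estimates −17.8 (SE 4.0) and a
between-arm difference of −11.3 (SE 4.5), i.e. the intervention produced
a significant additional reduction beyond the secular trend, with
estimates within sampling error of the planted effects.

The same objects are available from a console script:

```
ivswitch simulate --seed 1 --out cohort/        # write orders/labs/intake CSVs
ivswitch trigger  --cohort cohort/ --out reminders.csv
ivswitch its      --cohort cohort/ --break-month 14 --out fit.json --plot fig1.png
ivswitch fixture  --out fx/                     # packaged evaluation fixture
ivswitch review   --forms fx/forms.csv --out summary.json
```

Running `trigger` + `review` over the packaged fixture reproduces the
reference evaluation flow: 244 reminder-activated orders, 223 analysed
after discharge-day exclusion, 116 eligible for switch, 84 switched
(adherence 72%), and a second reminder round of 56 forms with 20 correct
switches.

## Layout

- `src/ivswitch/records.py` — medication orders, labs, intake records, CSV IO
- `src/ivswitch/rules.py` — trigger rule engine and `RuleConfig`
- `src/ivswitch/review.py` — switch categorisation and adherence
- `src/ivswitch/its.py` — `SegmentedITS` / `ControlledITS` models and results
- `src/ivswitch/simulate.py` — synthetic cohort and series generators
- `src/ivswitch/fixture.py` — deterministic detailed-evaluation fixture
- `src/ivswitch/cli.py` — `ivswitch` console script
- `docs/methods.md` — modelling and simulation notes
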