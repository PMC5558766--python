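# Methods notes

## Trigger algorithm

The engine evaluates every active iv antibiotic order independently at a
configurable morning run time (default 07:00).  Elapsed time is measured
in hours from the order start to the run time; reminder windows are
half-open intervals, by default [48, 72) h for the first reminder and
[96, 120) h for the second.  Half-open windows evaluated once a day at a
fixed clock time guarantee an order can match each window on at most one
run, with no double-triggering at boundary hours.  The second window may
issue a *first* reminder to an order whose first window fell entirely on
a weekend; the per-order cap (default 2) is enforced regardless.

Weekend runs are suppressed, not deferred: a reminder whose window passes
over a weekend is simply never issued.  This mirrors an organisational
reality of paper-based form distribution and is why weekend-window orders
surface as "not evaluable" downstream.

Exclusion rules, evaluated against the latest data available at the run
time:

| rule | fires when | default threshold |
|---|---|---|
| `crp_increase` | most recent CRP in the treatment episode exceeds the comparator | comparator = previous value |
| `neutropenia` | latest neutrophil count below threshold | 0.5·10⁹/L |
| `leukopenia` | latest leukocyte count below threshold | 1.0·10⁹/L |
| `no_oral_intake` | today's intake record flags parenteral-only medication or TPN | — |
| `severe_infection_regimen` | agent in the severe-infection list (carbapenems by default) or the order's high-dose flag is set | — |

Two deliberate policy choices:

1. **Missing data never excludes.**  Fewer than two CRP values, no blood
   count, no intake record — each yields "rule does not fire".  The
   reminder is advisory; the physician owns the decision, so the engine
   errs toward reminding.
2. **"CRP increasing" is a local trend** — the latest value strictly
   greater than the immediately preceding value within the episode
   (observations since the order start).  Comparing against the episode
   minimum or the first value is available via `RuleConfig.crp_mode`;
   the local trend is the default because a single high-but-falling CRP
   should not block a switch.  CRP history from before the order start is
   ignored: the rule is about the current treatment episode.

"Already switched" detection: an oral order for the same patient, for the
same agent or one of its protocol alternatives, starting within 24 h
(configurable) of the iv order's stop and no later than the current run.
High-dose status is carried as a boolean on the order rather than derived
from mg/day, because dose cut-offs are hospital policy per agent; a site
deploying the engine populates the flag from its own dose table.

## Review layer

Categorisation is a total function with fixed precedence: discharge-day
exclusion → evaluability (form returned, not weekend-generated) → the
four-criteria × switched/continued grid.  Eligibility (all four criteria
met, evaluable) and adherence (appropriate switches / eligible) follow
from the category counts; 0/0 adherence is reported as absent rather than
zero.  The reviewer's criteria are authoritative for appropriateness —
the engine's exclusion trace and the physician's impeding reasons are
reported but play no role in categorisation, which is why an engine-
eligible order can still be "not eligible for switch" on review.

## Segmented ITS model

Periods are coded t = 1..26 with the break at t = 14 (the first
post-intervention month), so `post_t = 1{t ≥ 14}` and the interaction
term `(t − 14)·post_t` is zero at the break month.  The reported columns
map onto the coefficients as pre-slope = β₁, level change = β₂,
post-slope = β₁ + β₃ with SE² = var β₁ + var β₃ + 2·cov(β₁, β₃); the slope
*change* β₃ is also exposed for readers who prefer that convention.
Estimation is plain OLS with t-distributed p-values on n − 4 degrees of
freedom; no autocorrelation adjustment is applied by default (an AR(1)
GLS option exists behind `fit(ar1=True)` but monthly aggregation of
independent prescriptions gives little serial structure).  Months with
zero orders are dropped from the regression input rather than imputed.

The controlled fit stacks both arms with a full set of arm interactions
(8 parameters).  Because the model is saturated in the arm factor, the
joint coefficient estimates coincide exactly with the standalone per-arm
fits (asserted to 1e−8 in tests); the difference terms are the
interaction coefficients, with pooled-residual standard errors.

Orders are binned by their **start** month: a prescription's ">72 h"
outcome is attributed to the conditions under which it was initiated.
The ">72 h" comparison is strict; exactly 72.0 h does not count.  Open
orders are censored at the observation-window end.

## Synthetic cohort generator

Defaults encode the reference study conditions: 13 + 13 months, monthly
order volumes ≈137/118 (intervention pre/post) and ≈367/330 (control),
pre-period baselines 50.5% and 49.8% of prescriptions > 72 h, level
changes −19.30 and −6.12 percentage points at the break, slope changes
+0.51 and +0.10 %/month, and pre-period median duration 4.0 days.  The
trajectory intercept is anchored so the *pre-period mean* equals the
configured baseline.  Monthly order counts are Poisson; each order draws
a duration from a two-component log-normal mixture — a narrow
"switched-early" component (median 44 h, σ = 0.19) and a long-course
component (σ = 0.25) — whose long-course weight is solved exactly for
that month's target P(duration > 72 h), and whose long-course median is
solved by root-finding for the period's median-duration target when the
pair is feasible.

A pair (P(>72 h) < 0.5, median > 3 days) is *jointly unattainable* for
any duration distribution (if fewer than half of durations exceed 72 h,
the median cannot exceed 72 h).  The reference post-intervention
conditions are of exactly this kind, presumably because the two outcomes
were computed on differently rounded data.  The generator resolves the
conflict in favour of the > 72 h fraction — the primary outcome — and
falls back to a typical 7-day long-course median; the simulated
post-period median is therefore ≈2.1 days rather than 3.2.  A related
knife-edge effect: when the month's target fraction is near 0.5 the
mixture median sits between the two well-separated components, so the
*monthly empirical median* is strongly bimodal across months.  Cohort-
level median-duration series are consequently noisy; series-level
simulation (`simulate_series`, which plants the segmented mean directly
with Gaussian noise) is the appropriate surface for median-outcome
parameter-recovery studies, and is what the recovery tests use.

Patient structure is minimal — one admission and one order per patient,
CRP sampled at three fixed offsets (decaying ×0.62/obs for most patients,
rising ×1.35 for a configurable 10%), one blood count, cytopenia
prevalences 2%/1%, parenteral-only intake for 5% of patients.  Within-
patient correlation, microbiology, resistance and clinical outcomes are
not modelled; nothing the package estimates depends on them, so passing
tests demonstrate correctness of the counting and regression machinery,
not realism of patient-level clinical trajectories.

The deterministic evaluation fixture (`fixture.py`) is hand-constructed,
seed-free, and exists to pin the counting logic: order start times are
laid out so the engine's own window/weekend rules yield exactly the
reference flow counts (see the module docstring for the geometry).  The
split of discharge exclusions and unreturned forms across the two
reminder rounds is not identifiable from the reference marginals; the
fixture places both entirely in round 1, which satisfies every marginal
simultaneously.

## Problem sizes and numerics

Parameter-recovery checks use 200 replicates of 26-point series (noise
σ = 4 percentage points for the fraction outcome, 0.25 days for the
median outcome — chosen to match the residual scale the configured
volumes imply, ≈ binomial sd at 137 orders/month).  Generator-calibration
checks pool ~1,780 pre-period intervention orders, where binomial noise
gives the pooled percentage an sd of ≈1.2 points.  OLS exactness is
asserted at 1e−8 against a direct normal-equations solve.  Unit-test
cohorts are scaled to ~1/4 volume; the full default configuration
(~12,000 orders, ~60,000 labs) simulates in about one second.

## Known limitations

- The review layer consumes recorded criteria booleans; it does not infer
  them from labs/cultures (in practice a specialist judges them).
- The generator's duration model cannot honour infeasible
  (fraction, median) target pairs, as above.
- No seasonality, autocorrelation (beyond the optional AR(1)), or
  multiple-outcome correction in the ITS layer.
- Weekend suppression assumes the configured run calendar; public
  holidays are not modelled.
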