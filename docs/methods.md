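# Methods

## Scope and model

dvtflow models the flow of suspected-DVT referrals from a commissioning
group's population through hospital diagnostics into anticoagulation
treatment delivered in hospital or in community services, under two
regimens (warfarin-based standard care and NOAC), and evaluates policy
scenarios that shift a fraction of patients to community services and a
fraction to NOAC. It is an activity/cost/value-for-money model: clinical
outcomes (bleeds, mortality, post-thrombotic syndrome) are out of scope,
as is any graphical front end.

The stochastic engine is a hand-built seeded event-queue kernel
(`engine.py`): future-event list on a heap, continuous clock in days,
resource pools with FIFO queues, and a fixed tiebreak for simultaneous
events (releases before seizes before arrivals, so an entity never
waits for a unit freed at the same instant). Pool capacity is
`max(1, round(headcount x DVT-allocation fraction))`; recorded staff
hours are the raw hands-on DVT service minutes, which keeps the hour
accounting exactly linear in the service durations.

## Pathway assumptions

* Referrals: nonhomogeneous Poisson, annual rate
  `base_population x referral_rate/1000 x (1+growth)^year`. Defaults:
  220,000 population, 1%/yr growth, 5-year horizon.
* Diagnostics: five sequential hospital steps (history, consultant
  exam, Wells score, D-dimer, ultrasound); a single positive/negative
  exit with probability `dvt_positive_fraction` (0.3 by default).
  Negative referrals still consume diagnostic staff time and are
  included in the hour KPIs.
* Treatment assignment: group and duration from the case mix; setting
  and regimen from two independent Bernoulli draws against the scenario
  fractions, so all four regimen x setting cells occur.
* Visits: evenly spaced over the course, count fixed by the regimen
  (9/14/24 standard, 2 NOAC). The first visit is always in hospital.
  Each follow-up of a community-managed patient is delivered at the
  hospital INR clinic with probability `hospital_retention` (rho,
  calibrated ~0.31) and by a community nurse otherwise. Every hospital
  INR visit (first or follow-up) takes nurse time plus a short
  haematologist review; the published doctor-hour table falls steeply
  with NOAC uptake, which is only possible if doctors attend routine
  INR visits, not just first attendances. Community visits are
  nurse-only.
* Horizon accounting: arrivals stop at the demand horizon; execution
  continues through a 450-day run-out so every admitted patient's
  course completes. KPIs are therefore the total activity generated by
  5 years of referrals (cohort accounting), the convention the
  expectation oracle linearises. Visits are counted at their start.
* Recurrent patients are a referral group, not a feedback loop.
* Durations expressed in months use 30.4375 days/month (Julian year).

The retention parameter rho is the one mechanism added beyond a pure
independent-split reading of the pathway. Without it, hospital visits
fall proportionally with the community fraction, and no parameter
choice can reproduce the published scenario grid within 10%: the
best-possible fit leaves the two headline scenario rows at ~12% error.
With a single retained-share parameter the interpretation is direct —
community services substitute for most but not all INR monitoring —
and the grid fits within the published bands.

## Randomness and reproducibility

All randomness flows from one `numpy` SeedSequence. Replications use
spawned child sequences; within a replication, per-patient uniforms
(diagnosis, group, duration, setting, regimen, per-visit retention) are
pre-drawn in a scenario-independent order. Two scenarios run from the
same replication seed therefore see identical patients and differ only
in policy thresholds: common random numbers, which makes between-
scenario differences sharp and scenario results independent of grid
order. Children are derived with explicit spawn keys rather than the
stateful `spawn()` so stream sharing is exact. A fixed base seed
reproduces every KPI bit-for-bit. Default replications: 30; default
base seed: 20221226.

## Expectation oracle

`expected_kpis` computes exact expected KPIs by linearising over the
aggregate duration mix, the diagnosis branch, and the four policy
cells; queueing delays shift timing, not cohort counts, under the
cohort accounting rule, so they do not enter. The replication means of
the engine must sit within 3 Monte-Carlo standard errors of the oracle
on random parameter draws — this equivalence is asserted in the test
suite and is the package's central self-check.

## Calibration of the reference configuration

The original model's 70 raw inputs are not published; the packaged
reference set is produced by `oracle.calibrate`, a bounded least-squares
fit of the oracle to the printed result tables, with relative residuals
(each target scaled by its printed value) so visit counts and
GBP-millions weigh comparably.

* Frozen (printed): visit schedules 9/14/24 and 2; 8-day LMWH phase;
  1%/yr growth; 5-year horizon; 220,000 population.
* Assumed (fixed from knowledge of NHS DVT services): positive fraction
  0.3; group fractions 0.40/0.35/0.25; LMWH GBP 7.12/day and warfarin
  GBP 0.06/day; ultrasound 12 min; headcounts and allocations; STAR
  feasibilities; `vfm_scale` = 1000.
* Calibrated (15 degrees of freedom): referral volume; a duration-mix
  tilt blending short- and long-course templates per group; rho;
  diagnostic nurse and consultant minutes; per-visit nurse/doctor/
  community-nurse minutes; first and follow-up visit unit costs; NOAC
  daily cost; nurse, doctor and radiologist hourly rates.

Targets are all 17 printed rows of the operational and financial
tables, with the baseline row weighted x6 because it is the hard gate:
the published model was validated to within 5% of observed data, and
the fitted baseline row reproduces the printed values to <= 1.7%.
Scenario rows are soft: the printed grid declines nonlinearly in the
community fraction in a way no fixed-parameter split can reproduce
(back-solving rho from single rows gives 0.09 for one headline row and
0.45 for another), so grid residuals up to ~19% remain on individual
cost components and are reported by the calibration op rather than
hidden. The headline scenario totals (visits, nurse hours, total cost
at the two most-discussed grid points) land within 10%. A consequence
worth stating plainly: the integer percentage reductions derived from
the fitted model (52/63/48/46 for the four headline comparisons) differ
by a few points from the printed 54/59/48/50; the corresponding
acceptance test records this honestly rather than papering over it.

Several calibrated unit values land at their plausibility bounds
(first visit GBP 60, community follow-up GBP 2, nurse GBP 100/h): the
printed tables imply effective unit costs that absorb unprinted
overheads, and these values should be read as model-internal effective
prices, not tariffs. The calibration warns when the Jacobian is rank
deficient (confounded parameter pairs are named); bound-stuck columns
legitimately trigger this on the reference fit.

The duration-mix tilt fits at its long end: ~74% of patients on
12-month courses (mean ~20.9 standard-care visits). That is long for a
general DVT cohort but is what the printed visit volume per patient
requires; it is consistent with a clinic caseload heavy in unprovoked
and recurrent disease on extended anticoagulation.

STAR benefit scores are backed out from one printed VfM row (the 20%
community / 10% NOAC scenario) given the oracle's patient counts and
intervention costs and the assumed feasibilities; intervention
expenditure is the cohort's care cost plus its treatment-visit staff
time (diagnostics precede the treatment decision and are not
attributed). Because per-patient intervention cost is policy-invariant
in this model, the scores are nearly constant across scenarios, and
the published qualitative ordering (NOAC > standard within a setting,
community > hospital within a regimen) holds at every grid point; the
scenario-to-scenario score variation in the published table is not
reproduced.

## Problem sizes and what the tests show

Full-scale runs use the calibrated demand (~2,100 referrals/yr, ~570
DVT-positive) for 30 replications; unit and property tests scale the
referral rate down ~20x, which leaves every mechanism — grouping,
regimens, retention, resources, costing — intact and only widens
Monte-Carlo noise. The synthetic conditions match the published study
design (one population, fixed growth, a 17-point policy grid); they do
not emulate seasonality, capacity crises, referral-mix drift or
clinical heterogeneity beyond the group/duration mix, so passing tests
demonstrate internal consistency and faithfulness to the printed
tables, not predictive validity for a specific real service.

## Numerical choices

* Simultaneous-event order: release < seize < arrival, then insertion
  order; deterministic and documented as priority constants.
* No warm-up: the system starts empty, as a new-service model.
* Multi-resource hospital first visits acquire nurse, then doctor, then
  bed in a fixed order; waiting is attributed to the nurse queue.
* Probability distributions in the configuration must sum to 1 within
  1e-9; validation reports every violated rule with its field path,
  warnings (e.g. demand inconsistent with the documented prevalence
  metadata by >20%) never block a run. The packaged reference set
  deliberately carries that prevalence warning: the published demand
  facts are mutually inconsistent, and the calibrated volume follows
  the activity tables, not the prevalence figure.
* 95% intervals are Student-t on replication means; a single
  replication flags intervals unavailable rather than reporting 0.

## Known limitations

* The retention share is constant across regimens, durations and years;
  the printed grid's nonlinearity suggests the original model had
  additional mechanics (or single-run noise) that are unknowable from
  the text.
* Resource capacities are generous in the reference set, so queueing is
  rare; the queueing machinery is exercised by tests (M/D/1 against the
  Pollaczek-Khinchine formula) but the published tables contain no wait
  information to calibrate against.
* Nominal GBP throughout; no discounting over the 5-year horizon.
* The VfM layer scores and ranks; it does not implement decision
  conferencing, elicitation tooling or budget optimisation.
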