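# dvtflow

A discrete-event simulator of deep-vein-thrombosis (DVT) care pathways
with STAR value-for-money scoring, for health-service planners asking a
concrete question: if a commissioning group shifts a share of
anticoagulation patients into community services, and puts a share of
them on NOACs instead of warfarin, what happens to hospital clinic
activity, staff hours, cost, and value for money?

## The model

Suspected-DVT referrals arrive as a nonhomogeneous Poisson process with
piecewise-constant annual rate

```
lambda_y = P * r / 1000 * (1 + g)^y ,   y = 0 .. Y-1
```

(population *P*, referral rate *r* per 1,000/yr, growth *g*, horizon *Y*
years). Each referral passes a five-step hospital diagnostic sequence
(history, consultant exam, Wells score, D-dimer, ultrasound), each step
seizing its staffed resource pool with FIFO queueing. With probability
*q* the patient is DVT-positive and receives a treatment plan:

* **group** ~ {provoked, unprovoked, recurrent}, **duration** *d* ∈
  {3, 6, 12} months from the group's mix;
* **regimen**: standard care (8 days LMWH, then warfarin; 9/14/24 INR
  clinic visits for 3/6/12 months) or NOAC (2 INR visits regardless of
  duration), drawn with the scenario's NOAC fraction;
* **setting**: hospital or community, drawn independently with the
  scenario's community fraction.

Visits are evenly spaced over the course. The first visit is always at
the hospital clinic; a community-managed patient's follow-ups are
delivered by community nurses except for a retained share ρ that stays
at the hospital INR clinic. Hospital visits take nurse time plus a short
haematologist review (and a bed at the first visit); community visits
take community-nurse time only. KPIs follow the published conventions:
hospital INR visits count hospital-delivered attendances, nurse hours
pool both settings, costs decompose as standard care + NOAC + staff.

A closed-form **expectation oracle** computes the exact expected value
of every KPI for any (parameters, scenario) pair. It serves two roles:
verifying the stochastic engine (replication means must sit within
Monte-Carlo error of the closed form) and calibrating the unprinted
parameters of the packaged reference configuration against the
published baseline and scenario result tables (the original model's 70
raw inputs are in an unavailable supplement). Every parameter carries a
provenance tag: `printed`, `calibrated`, or `assumed`.

The **STAR layer** (Socio-Technical Allocation of Resources) scores each
intervention (regimen × setting) as

```
VfM = vfm_scale * n * benefit * feasibility / cost
```

with *n* and cost from the simulation and benefit/feasibility from
stakeholder elicitation.

## Worked example

```python
from dvtflow import reference_parameters, run_replications
from dvtflow.scenarios import BASELINE

params = reference_parameters()
results, _ = run_replications(params, BASELINE, n_reps=5, seed=20221226)
print(round(results.means["hospital_inr_visits"]))
print(round(results.means["nurse_hours"]))
print(round(results.means["total_cost"]))
```

prints (seed 20221226, 5 replications)

```
59497
9338
4463492
```

— about 60,000 hospital anticoagulation-clinic visits, 9,500 nurse
hours and £4.5M total cost generated over 5 years by the baseline
policy (everyone on warfarin, in hospital). Moving to 50% community /
50% NOAC (`ScenarioSpec("s16", 0.5, 0.5)`) drops visits to ~22,700 and
cost to ~£2.45M. The `examples/` directory has one narrative script per
capability: baseline run, grid sweep, oracle-vs-engine check,
calibration, and value-for-money ranking; the same functionality is
available from the shell via `dvtflow run|grid|calibrate|vfm|validate`.

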