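"""Re-run the reference calibration against the printed result tables.

The published model's 70 raw inputs live in an unavailable supplement,
so the package back-fits the unprinted ones: the expectation oracle is
least-squares-fitted to the printed operational and financial tables
(all 17 scenario rows, baseline weighted). This example reproduces that
fit and prints the residuals on the rows a user cares most about.
"""

import warnings

from dvtflow.oracle import reference_calibration_problem, calibrate
from dvtflow.reference import skeleton_parameters

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # parameters at bounds look rank-deficient
    result = calibrate(reference_calibration_problem(), skeleton_parameters())

print("fitted calibrated parameters:")
print(f"  referrals/1000/yr      {result.params.demand.referral_rate:8.3f}")
print(f"  hospital retention     {result.params.pathway.hospital_retention:8.3f}")
print(f"  nurse min/hosp visit   {result.params.resources.service_minutes['hospital_visit_nurse']:8.3f}")
print(f"  doctor min/hosp visit  {result.params.resources.service_minutes['hospital_visit_doctor']:8.3f}")
print(f"  follow-up cost (hosp)  {result.params.costs.followup_visit['hospital']:8.2f} GBP")
print(f"  NOAC cost/day          {result.params.costs.drug_cost_per_day['NOAC']:8.3f} GBP")

print("\nrelative residuals vs the printed tables:")
for label in ("Baseline", "Scenario 8", "Scenario 16"):
    rows = [(t, r) for t, r in result.residuals if t.scenario.label == label]
    worst = max(rows, key=lambda x: abs(x[1]))
    print(f"  {label:12s} worst |error| {abs(worst[1]):6.2%} on {worst[0].kpi}")
print(f"  all 17 rows  worst |error| {result.max_abs_residual():6.2%}")

print()
print("The baseline row fits inside the published 5% validation band; the")
print("scenario rows carry larger residuals because the printed grid is")
print("nonlinear in ways a fixed-parameter pathway cannot reproduce, and")
print("those residuals are reported rather than hidden.")
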