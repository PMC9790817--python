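"""Run the baseline scenario (all patients on warfarin, in hospital).

Builds nothing: the packaged reference configuration is loaded, the
5-year baseline is simulated for a handful of replications, and the
headline KPIs are printed with their 95% confidence half-widths.
"""

from dvtflow import reference_parameters, run_replications
from dvtflow.scenarios import BASELINE

params = reference_parameters()
results, _ = run_replications(params, BASELINE, n_reps=5, seed=20221226)

print(f"Baseline scenario, {results.n_reps} replications over "
      f"{params.demand.horizon_years} years")
for kpi in ("hospital_inr_visits", "community_visits", "nurse_hours",
            "doctor_hours", "standard_care_cost", "noac_cost", "staff_cost",
            "total_cost"):
    print(f"  {kpi:22s} {results.means[kpi]:14,.1f}  +/- {results.half_widths[kpi]:,.1f}")

print()
print("Hospital INR visits is the headline activity metric: every")
print("anticoagulation-clinic attendance (first and follow-up) by the ~570")
print("DVT-positive patients referred each year. With 0% NOAC and 0%")
print("community care the 5-year total sits near 60,000 visits, and the")
print("NOAC cost is structurally zero.")
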