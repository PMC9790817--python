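"""KPI accounting: operational and financial outcomes per replication.

Counting conventions. "Total hospital INR visits" counts visits delivered
at the hospital anticoagulation clinic (first and follow-up), because the
published scenario results show this count falling as patients shift to
community services; community-delivered follow-ups are a separate KPI.
Nurse hours pool hospital and community nurses together. Visits are
counted at their start time. Diagnostic work for referrals that turn out
DVT-negative consumes real staff time and is included in the hour KPIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .params import DAYS_PER_MONTH, CostSchedule
from .pathway import RunLog


@dataclass
class OperationalKPIs:
    hospital_inr_visits: int
    community_visits: int
    nurse_hours: float
    doctor_hours: float
    radiologist_hours: float  # tracked internally, not a headline figure
    mean_visit_wait_min: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class FinancialKPIs:
    standard_care_cost: float
    noac_cost: float
    staff_cost: float

    @property
    def total_cost(self) -> float:
        return self.standard_care_cost + self.noac_cost + self.staff_cost

    def as_dict(self) -> dict[str, float]:
        d = dict(self.__dict__)
        d["total_cost"] = self.total_cost
        return d


@dataclass
class InterventionUsage:
    """Per regimen x setting cohort: the STAR layer's simulation inputs."""

    intervention: str
    n_patients: int
    cost: float  # care cost + cohort's treatment staff cost, GBP


def compute_operational_kpis(log: RunLog) -> OperationalKPIs:
    hosp = comm = 0
    waits = []
    for pat in log.patients:
        for v in pat.visits:
            if v.setting == "hospital":
                hosp += 1
            else:
                comm += 1
            waits.append(v.wait_min)
    mins = log.minutes_by_resource
    nurse_hours = (mins.get("nurse", 0.0) + mins.get("cs_nurse", 0.0)) / 60.0
    return OperationalKPIs(
        hospital_inr_visits=hosp,
        community_visits=comm,
        nurse_hours=nurse_hours,
        doctor_hours=mins.get("doctor", 0.0) / 60.0,
        radiologist_hours=mins.get("radiologist", 0.0) / 60.0,
        mean_visit_wait_min=float(np.mean(waits)) if waits else 0.0,
    )


def drug_cost(regimen_name: str, duration_months: int, costs: CostSchedule,
              drug_phases) -> float:
    """Drug expenditure over one treatment course.

    Fixed-length phases are consumed in order; a ``remainder`` phase covers
    the rest of the course (standard care: 8 days LMWH then warfarin; NOAC:
    tablets throughout).
    """
    total_days = duration_months * DAYS_PER_MONTH
    remaining = total_days
    cost = 0.0
    for phase in drug_phases:
        days = remaining if phase.length_days == "remainder" else min(
            float(phase.length_days), remaining)
        try:
            per_day = costs.drug_cost_per_day[phase.drug]
        except KeyError:
            raise ConfigurationError(
                f"no unit cost for drug '{phase.drug}' (regimen '{regimen_name}')"
            ) from None
        cost += days * per_day
        remaining -= days
        if remaining <= 0:
            break
    return cost


def _visit_cost(kind: str, setting: str, costs: CostSchedule) -> float:
    table = costs.first_visit if kind == "first" else costs.followup_visit
    try:
        return table[setting]
    except KeyError:
        raise ConfigurationError(f"no unit cost for {kind} visit in setting '{setting}'") from None


def compute_financial_kpis(log: RunLog, costs: CostSchedule,
                           regimens=None) -> tuple[FinancialKPIs, list[InterventionUsage]]:
    """Financial KPIs plus the per-intervention breakdown used by STAR.

    Standard-care and NOAC costs cover each cohort's visits and drugs;
    staff cost is hours x hourly rates over all pools. The intervention
    breakdown additionally allocates the *treatment-visit* staff minutes to
    each cohort (diagnostic work precedes the treatment decision and is not
    attributed to an intervention).
    """
    care = {"standard": 0.0, "NOAC": 0.0}
    cohorts: dict[str, dict[str, float]] = {}
    rates = costs.staff_hourly_rate
    for pat in log.patients:
        plan = pat.plan
        if plan is None:
            continue
        visit_cost = sum(_visit_cost(v.kind, v.setting, costs) for v in pat.visits)
        phases = regimens[plan.regimen].drug_phases if regimens else _DEFAULT_PHASES[plan.regimen]
        dc = drug_cost(plan.regimen, plan.duration_months, costs, phases)
        care[plan.regimen] += visit_cost + dc
        label = f"{plan.regimen}_{plan.setting}"
        cell = cohorts.setdefault(label, {"n": 0, "cost": 0.0})
        cell["n"] += 1
        staff_min = sum(
            v.nurse_min * rates.get("cs_nurse" if v.setting == "community" else "nurse", 0.0)
            + v.doctor_min * rates.get("doctor", 0.0)
            for v in pat.visits)
        cell["cost"] += visit_cost + dc + staff_min / 60.0

    staff_cost = 0.0
    for pool, minutes in log.minutes_by_resource.items():
        try:
            rate = rates[pool] if pool != "bed" else 0.0
        except KeyError:
            raise ConfigurationError(f"no hourly rate for staff pool '{pool}'") from None
        staff_cost += minutes / 60.0 * rate

    fin = FinancialKPIs(standard_care_cost=care["standard"], noac_cost=care["NOAC"],
                        staff_cost=staff_cost)
    usage = [InterventionUsage(lbl, int(c["n"]), c["cost"]) for lbl, c in sorted(cohorts.items())]
    return fin, usage


class _Phases:
    def __init__(self, drug, length):
        self.drug, self.length_days = drug, length


_DEFAULT_PHASES = {
    "standard": [_Phases("LMWH", 8), _Phases("warfarin", "remainder")],
    "NOAC": [_Phases("NOAC", "remainder")],
}


# ---------------------------------------------------------------------------
# replication aggregation


@dataclass
class SimulationResults:
    """Replication statistics for one scenario."""

    scenario_label: str
    n_reps: int
    per_rep: list[dict[str, float]]  # KPI name -> value, one dict per replication
    means: dict[str, float] = field(default_factory=dict)
    half_widths: dict[str, float] | None = None  # 95% t-interval half-widths

    def kpi_array(self, name: str) -> np.ndarray:
        return np.array([r[name] for r in self.per_rep])


def kpi_dict(op: OperationalKPIs, fin: FinancialKPIs) -> dict[str, float]:
    d = op.as_dict()
    d.update(fin.as_dict())
    return d


def aggregate_replications(label: str, per_rep: list[dict[str, float]]) -> SimulationResults:
    """Means and 95% t-based half-widths per KPI.

    With a single replication only means are reported and interval
    estimates are flagged unavailable (``half_widths is None``).
    """
    if not per_rep:
        raise ConfigurationError("no replications to aggregate")
    names = per_rep[0].keys()
    means = {k: float(np.mean([r[k] for r in per_rep])) for k in names}
    if len(per_rep) < 2:
        return SimulationResults(label, len(per_rep), per_rep, means, None)
    n = len(per_rep)
    tcrit = stats.t.ppf(0.975, n - 1)
    hw = {}
    for k in names:
        sd = float(np.std([r[k] for r in per_rep], ddof=1))
        hw[k] = tcrit * sd / math.sqrt(n)
    return SimulationResults(label, n, per_rep, means, hw)
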