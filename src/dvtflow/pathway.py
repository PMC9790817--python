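"""The DVT care pathway model.

Patients arrive on referral (GP, A&E, outpatient clinic or community
service), pass through a five-step diagnostic sequence in hospital
(history, consultant examination, Wells score, D-dimer blood test,
ultrasound), and are either discharged or put on an anticoagulation
treatment plan: a regimen (warfarin-based standard care or NOAC), a
duration (3, 6 or 12 months) drawn from the patient group's mix, and a
care setting (hospital or community) drawn from the policy scenario.

Visit rules. The first treatment visit is always at the hospital clinic.
For hospital-managed patients every follow-up is a hospital INR visit too.
For community-managed patients each follow-up is delivered by a community
nurse, except that with probability ``pathway.hospital_retention`` it is
still an INR check at the hospital clinic -- community services substitute
for most, not all, monitoring. Hospital visits occupy a nurse and a short
haematologist review (plus a bed at the first visit); community visits
occupy a community nurse only.

Randomness is organised for common random numbers: all per-patient
uniforms are pre-drawn in a scenario-independent order, so two scenarios
run from the same replication seed see identical patients and differ only
in the policy thresholds applied to those draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import (PRIORITY_ARRIVAL, PRIORITY_SEIZE, MINUTES_PER_DAY,
                     ResourcePool, Simulator)
from .errors import ConfigurationError, DomainError
from .params import (DAYS_PER_MONTH, DAYS_PER_YEAR, DIAGNOSTIC_STEPS, DURATIONS_MONTHS,
                     GROUPS, GroupMix, ParameterSet, RegimenDef)
from .scenarios import ScenarioSpec

REFERRAL_SOURCES = ("GP", "A&E", "outpatient", "community")

#: Extra run-out beyond the arrival horizon so treatments of patients
#: referred inside the window complete (longest plan is 12 months).
RUNOUT_DAYS = 450.0


@dataclass
class Visit:
    scheduled_day: float
    start_day: float
    kind: str  # "first" | "follow_up"
    setting: str  # "hospital" | "community"
    nurse_min: float
    doctor_min: float
    wait_min: float


@dataclass
class TreatmentPlan:
    regimen: str
    duration_months: int
    setting: str
    planned_visits: int
    #: per-visit delivery setting, resolved at planning time (index 0 is
    #: the first visit, always hospital)
    visit_settings: list[str] = field(default_factory=list)


@dataclass
class PatientRecord:
    id: int
    arrival_day: float
    referral_source: str
    group: str | None = None
    diagnosis: str = "pending"  # "DVT-positive" | "negative-discharged"
    plan: TreatmentPlan | None = None
    visits: list[Visit] = field(default_factory=list)
    diag_wait_min: float = 0.0


# ---------------------------------------------------------------------------
# elementary operations


def generate_arrivals(demand, horizon_years: int | None, rng: np.random.Generator) -> np.ndarray:
    """Referral times (days) from a piecewise-constant-rate Poisson process.

    The annual rate is lambda_0 * (1 + growth)^y in year y, with
    lambda_0 = base_population * referral_rate / 1000.
    """
    lam0 = demand.base_population * demand.referral_rate / 1000.0
    if demand.referral_rate == 0:
        return np.empty(0)
    if lam0 <= 0:
        raise ConfigurationError("arrival rate must be positive (base_population * referral_rate)")
    years = int(horizon_years if horizon_years is not None else demand.horizon_years)
    times = []
    for y in range(years):
        lam = lam0 * (1.0 + demand.annual_growth) ** y
        n = rng.poisson(lam)
        times.append(y * DAYS_PER_YEAR + np.sort(rng.random(n)) * DAYS_PER_YEAR)
    return np.concatenate(times) if times else np.empty(0)


def visit_count(regimen: RegimenDef, duration_months: int) -> int:
    """Planned INR clinic visits for a regimen/duration pair (pure lookup)."""
    try:
        return regimen.visits_by_duration[duration_months]
    except KeyError:
        raise DomainError(
            f"regimen '{regimen.name}' defines no visit count for a "
            f"{duration_months}-month course"
        ) from None


def schedule_visit_times(plan: TreatmentPlan, start_day: float) -> list[float]:
    """Evenly spaced visit days: first at ``start_day``, last at start + duration."""
    v = plan.planned_visits
    span = plan.duration_months * DAYS_PER_MONTH
    if v == 1:
        return [start_day]
    return [start_day + i * span / (v - 1) for i in range(v)]


def _sample_categorical(u: float, items: list, probs: list[float]):
    acc = 0.0
    for item, p in zip(items, probs):
        acc += p
        if u < acc:
            return item
    return items[-1]


def build_plan(scenario: ScenarioSpec, mix: GroupMix, regimens: dict[str, RegimenDef],
               retention: float, u_group: float, u_dur: float, u_cs: float,
               u_noac: float, u_ret: np.ndarray) -> tuple[str, TreatmentPlan]:
    """Resolve group, duration, setting, regimen and per-visit delivery.

    The community and NOAC draws are independent Bernoullis against the
    scenario fractions. ``u_ret`` supplies one uniform per potential
    follow-up for the retention rule.
    """
    groups = list(GROUPS)
    group = _sample_categorical(u_group, groups, [mix.group_fractions[g] for g in groups])
    durs = list(DURATIONS_MONTHS)
    duration = _sample_categorical(u_dur, durs, [mix.duration_mix[group][d] for d in durs])
    setting = "community" if u_cs < scenario.frac_cs else "hospital"
    regimen = "NOAC" if u_noac < scenario.frac_noac else "standard"
    n_visits = visit_count(regimens[regimen], duration)
    settings = ["hospital"]  # first visit is always at the hospital clinic
    for j in range(n_visits - 1):
        if setting == "hospital":
            settings.append("hospital")
        else:
            settings.append("hospital" if u_ret[j] < retention else "community")
    plan = TreatmentPlan(regimen=regimen, duration_months=duration, setting=setting,
                         planned_visits=n_visits, visit_settings=settings)
    return group, plan


def assign_treatment(scenario: ScenarioSpec, mix: GroupMix,
                     regimens: dict[str, RegimenDef], retention: float,
                     rng: np.random.Generator) -> tuple[str, TreatmentPlan]:
    """Draw one treatment plan for a confirmed patient (rng-driven form)."""
    u = rng.random(4)
    u_ret = rng.random(max(max(r.visits_by_duration.values()) for r in regimens.values()))
    return build_plan(scenario, mix, regimens, retention, u[0], u[1], u[2], u[3], u_ret)


# ---------------------------------------------------------------------------
# whole-scenario runs


@dataclass
class RunLog:
    """Everything one replication produced."""

    scenario: ScenarioSpec
    horizon_days: float
    n_referrals: int
    patients: list[PatientRecord]
    pools: dict[str, ResourcePool]
    trace: list[tuple]

    @property
    def minutes_by_resource(self) -> dict[str, float]:
        return {name: pool.busy_minutes for name, pool in self.pools.items()}


def make_pools(p: ParameterSet) -> dict[str, ResourcePool]:
    return {
        name: ResourcePool(name, p.resources.headcount.get(name, 0.0),
                           p.resources.dvt_allocation.get(name, 1.0))
        for name in p.resources.headcount
    }


def _diag_minutes(p: ParameterSet) -> list[tuple[str, str, float]]:
    steps = []
    for activity, pool in DIAGNOSTIC_STEPS:
        try:
            minutes = p.resources.service_minutes[activity]
        except KeyError:
            raise ConfigurationError(
                f"no service duration configured for diagnostic step '{activity}'"
            ) from None
        steps.append((activity, pool, minutes))
    return steps


class _PatientDraws:
    """Scenario-independent uniforms, one block per arriving patient."""

    def __init__(self, rng: np.random.Generator, n: int, max_followups: int) -> None:
        self.u_pos = rng.random(n)
        self.u_group = rng.random(n)
        self.u_dur = rng.random(n)
        self.u_cs = rng.random(n)
        self.u_noac = rng.random(n)
        self.u_source = rng.random(n)
        self.u_ret = rng.random((n, max_followups)) if n else np.empty((0, max_followups))


def run_scenario(p: ParameterSet, scenario: ScenarioSpec,
                 seed: int | np.random.SeedSequence,
                 collect_trace: bool = False) -> RunLog:
    """Simulate one replication of one policy scenario.

    Arrivals stop at the demand horizon; execution continues through a
    fixed run-out so every admitted patient's treatment completes. KPIs
    therefore measure the total activity generated by the horizon's
    referrals (cohort accounting).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # derive children statelessly: spawn() advances the parent's spawn
    # counter, which would break stream sharing across scenarios
    ss_arrivals, ss_patients = (
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (k,))
        for k in (0, 1))
    rng_arr = np.random.default_rng(ss_arrivals)

    arrivals = generate_arrivals(p.demand, p.demand.horizon_years, rng_arr)
    n = len(arrivals)
    max_follow = max(max(r.visits_by_duration.values()) for r in p.regimens.values()) - 1
    draws = _PatientDraws(np.random.default_rng(ss_patients), n, max_follow)

    sim = Simulator()
    pools = make_pools(p)
    diag_steps = _diag_minutes(p)
    sm = p.resources.service_minutes
    try:
        m_nurse_h = sm["hospital_visit_nurse"]
        m_doctor_h = sm["hospital_visit_doctor"]
        m_nurse_c = sm["community_visit_nurse"]
        m_bed = sm["bed_occupancy_first_visit"]
    except KeyError as exc:
        raise ConfigurationError(f"no service duration configured for visit activity {exc}") from exc

    q = p.demand.dvt_positive_fraction
    retention = p.pathway.hospital_retention
    src_names = list(p.pathway.referral_source_mix)
    src_probs = [p.pathway.referral_source_mix[s] for s in src_names]
    patients: list[PatientRecord] = []
    trace: list[tuple] = []

    def start_treatment(sim: Simulator, pat: PatientRecord, i: int) -> None:
        group, plan = build_plan(scenario, p.mix, p.regimens, retention,
                                 draws.u_group[i], draws.u_dur[i], draws.u_cs[i],
                                 draws.u_noac[i], draws.u_ret[i])
        pat.group = group
        pat.plan = plan
        times = schedule_visit_times(plan, sim.now)
        for k, (day, setting) in enumerate(zip(times, plan.visit_settings)):
            kind = "first" if k == 0 else "follow_up"
            sim.schedule(day, PRIORITY_ARRIVAL,
                         _visit_action(pat, kind, setting), tag="visit")

    def _visit_action(pat: PatientRecord, kind: str, setting: str):
        def execute(sim: Simulator) -> None:
            execute_visit(sim, pools, pat, kind, setting, m_nurse_h, m_doctor_h,
                          m_nurse_c, m_bed, trace if collect_trace else None)
        return execute

    def diagnose_action(pat: PatientRecord, i: int, step: int):
        def run_step(sim: Simulator) -> None:
            if step == len(diag_steps):
                if draws.u_pos[i] < q:
                    pat.diagnosis = "DVT-positive"
                    start_treatment(sim, pat, i)
                else:
                    pat.diagnosis = "negative-discharged"
                return
            activity, pool_name, minutes = diag_steps[step]

            def on_start(t: float, wait: float) -> None:
                pat.diag_wait_min += wait * MINUTES_PER_DAY
                if collect_trace:
                    trace.append(("service", t, pat.id, pool_name, activity, minutes,
                                  wait * MINUTES_PER_DAY))
                sim.schedule(t + minutes / MINUTES_PER_DAY, PRIORITY_SEIZE,
                             diagnose_action(pat, i, step + 1), tag=f"diag:{activity}")

            pools[pool_name].request(sim, minutes, on_start)
        return run_step

    for i, day in enumerate(arrivals):
        pat = PatientRecord(id=i, arrival_day=float(day),
                            referral_source=_sample_categorical(
                                draws.u_source[i], src_names, src_probs))
        patients.append(pat)
        sim.schedule(float(day), PRIORITY_ARRIVAL, diagnose_action(pat, i, 0), tag="arrival")

    horizon_days = p.demand.horizon_years * DAYS_PER_YEAR
    sim.run_until(horizon_days + RUNOUT_DAYS)
    return RunLog(scenario=scenario, horizon_days=horizon_days, n_referrals=n,
                  patients=patients, pools=pools, trace=trace)


def execute_visit(sim: Simulator, pools: dict[str, ResourcePool], pat: PatientRecord,
                  kind: str, setting: str, m_nurse_h: float, m_doctor_h: float,
                  m_nurse_c: float, m_bed: float, trace: list | None) -> None:
    """Deliver one treatment visit, seizing the setting's resources.

    Hospital visits: nurse plus a haematologist INR review, and a bed at
    the first visit. Community visits: community nurse only. The visit is
    counted at the start of its nurse service.
    """
    scheduled = sim.now

    if setting == "community":
        def on_start(t: float, wait: float) -> None:
            v = Visit(scheduled, t, kind, "community", m_nurse_c, 0.0,
                      wait * MINUTES_PER_DAY)
            pat.visits.append(v)
            if trace is not None:
                trace.append(("visit", t, pat.id, kind, "community", v.wait_min))
                trace.append(("service", t, pat.id, "cs_nurse", "community_visit",
                              m_nurse_c, v.wait_min))
        pools["cs_nurse"].request(sim, m_nurse_c, on_start)
        return

    def on_nurse_start(t: float, wait: float) -> None:
        v = Visit(scheduled, t, kind, "hospital", m_nurse_h, m_doctor_h,
                  wait * MINUTES_PER_DAY)
        pat.visits.append(v)
        if trace is not None:
            trace.append(("visit", t, pat.id, kind, "hospital", v.wait_min))
            trace.append(("service", t, pat.id, "nurse", "hospital_visit",
                          m_nurse_h, v.wait_min))

        def on_doctor_start(td: float, wd: float) -> None:
            if trace is not None:
                trace.append(("service", td, pat.id, "doctor", "inr_review",
                              m_doctor_h, wd * MINUTES_PER_DAY))
        pools["doctor"].request(sim, m_doctor_h, on_doctor_start)
        if kind == "first":
            pools["bed"].request(sim, m_bed)

    pools["nurse"].request(sim, m_nurse_h, on_nurse_start)
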