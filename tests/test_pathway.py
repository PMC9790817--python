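"""Pathway mechanics: arrivals, assignment, visits, retention."""

from __future__ import annotations

import numpy as np
import pytest

from dvtflow import DomainError, run_scenario, visit_count
from dvtflow.params import DAYS_PER_MONTH
from dvtflow.pathway import TreatmentPlan, build_plan, generate_arrivals, schedule_visit_times
from dvtflow.scenarios import ScenarioSpec

BASE = ScenarioSpec("base", 0.0, 0.0)


class TestArrivals:
    def test_zero_referral_rate_gives_null_process(self, ref_params, rng):
        d = ref_params.demand.model_copy(update={"referral_rate": 0.0})
        assert len(generate_arrivals(d, 5, rng)) == 0

    def test_mean_count_matches_poisson_rate(self, ref_params):
        # lambda_0 = 500/yr over 1 year, zero growth: mean within 3 SE of 500
        d = ref_params.demand.model_copy(update={
            "base_population": 1000.0, "referral_rate": 500.0, "annual_growth": 0.0})
        counts = [len(generate_arrivals(d, 1, np.random.default_rng(s))) for s in range(400)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 500.0) < 3 * se

    def test_growth_compounds_the_annual_rate(self, ref_params):
        # doubling growth: year-2 expected count is twice year-1's
        d = ref_params.demand.model_copy(update={
            "base_population": 1000.0, "referral_rate": 300.0, "annual_growth": 1.0})
        year2 = []
        for s in range(300):
            t = generate_arrivals(d, 2, np.random.default_rng(s))
            year2.append(np.sum(t >= 365.25))
        se = np.std(year2, ddof=1) / np.sqrt(len(year2))
        assert abs(np.mean(year2) - 600.0) < 3 * se

    def test_times_are_sorted_within_run(self, ref_params, rng):
        t = generate_arrivals(ref_params.demand, 2, rng)
        assert np.all(np.diff(t) >= 0) or len(t) < 2


class TestVisitSchedule:
    @pytest.mark.parametrize("regimen,duration,expected",
                             [("standard", 3, 9), ("standard", 6, 14), ("standard", 12, 24),
                              ("NOAC", 3, 2), ("NOAC", 6, 2), ("NOAC", 12, 2)])
    def test_visit_count_lookup(self, ref_params, regimen, duration, expected):
        assert visit_count(ref_params.regimens[regimen], duration) == expected

    def test_unknown_duration_is_a_domain_error(self, ref_params):
        with pytest.raises(DomainError, match="9-month"):
            visit_count(ref_params.regimens["standard"], 9)

    def test_standard_3_month_schedule_spans_the_course(self):
        plan = TreatmentPlan("standard", 3, "hospital", 9)
        times = schedule_visit_times(plan, 0.0)
        assert len(times) == 9
        assert times[0] == 0.0
        assert times[-1] == pytest.approx(3 * DAYS_PER_MONTH)
        assert np.allclose(np.diff(times), np.diff(times)[0])  # even spacing

    def test_noac_12_month_schedule_is_two_points(self):
        plan = TreatmentPlan("NOAC", 12, "community", 2)
        assert schedule_visit_times(plan, 0.0) == pytest.approx([0.0, 365.25])

    def test_schedule_length_always_equals_planned_visits(self, ref_params, rng):
        for _ in range(50):
            reg = rng.choice(["standard", "NOAC"])
            dur = int(rng.choice([3, 6, 12]))
            n = visit_count(ref_params.regimens[reg], dur)
            plan = TreatmentPlan(reg, dur, "hospital", n)
            assert len(schedule_visit_times(plan, float(rng.random() * 100))) == n


class TestAssignment:
    def _plans(self, p, scenario, n, seed=3):
        g = np.random.default_rng(seed)
        u = g.random((n, 4))
        u_ret = g.random((n, 23))
        return [build_plan(scenario, p.mix, p.regimens, p.pathway.hospital_retention,
                           *u[i], u_ret[i]) for i in range(n)]

    def test_baseline_is_all_standard_hospital(self, ref_params):
        for _, plan in self._plans(ref_params, ScenarioSpec("b", 0, 0), 300):
            assert (plan.regimen, plan.setting) == ("standard", "hospital")
            assert all(s == "hospital" for s in plan.visit_settings)

    def test_full_shift_is_all_noac_community(self, ref_params):
        for _, plan in self._plans(ref_params, ScenarioSpec("x", 1, 1), 300):
            assert (plan.regimen, plan.setting) == ("NOAC", "community")
            assert plan.visit_settings[0] == "hospital"  # first visit rule

    def test_splits_are_independent(self, ref_params):
        n = 10_000
        plans = self._plans(ref_params, ScenarioSpec("h", 0.5, 0.5), n)
        cells = {}
        for _, plan in plans:
            cells[(plan.regimen, plan.setting)] = cells.get((plan.regimen, plan.setting), 0) + 1
        se = np.sqrt(0.25 * 0.75 / n)
        for count in cells.values():
            assert abs(count / n - 0.25) < 3 * se
        assert len(cells) == 4  # all four regimen x setting cells occur

    def test_community_followups_are_retained_at_the_hospital_rate(self, ref_params):
        rho = ref_params.pathway.hospital_retention
        plans = self._plans(ref_params, ScenarioSpec("c", 1.0, 0.0), 3000)
        retained = total = 0
        for _, plan in plans:
            followups = plan.visit_settings[1:]
            retained += sum(s == "hospital" for s in followups)
            total += len(followups)
        se = np.sqrt(rho * (1 - rho) / total)
        assert abs(retained / total - rho) < 3 * se

    def test_group_mix_matches_configured_fractions(self, ref_params):
        n = 8000
        groups = [g for g, _ in self._plans(ref_params, BASE, n)]
        for name, frac in ref_params.mix.group_fractions.items():
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(groups.count(name) / n - frac) < 3.5 * se


class TestScenarioRun:
    def test_all_positive_fraction_sends_everyone_to_treatment(self, small_params):
        p = small_params
        p.demand.dvt_positive_fraction = 1.0
        log = run_scenario(p, BASE, seed=5)
        assert log.patients and all(pat.plan is not None for pat in log.patients)

    def test_zero_positive_fraction_discharges_everyone(self, small_params):
        p = small_params
        p.demand.dvt_positive_fraction = 0.0
        log = run_scenario(p, BASE, seed=5)
        assert log.patients
        assert all(pat.diagnosis == "negative-discharged" for pat in log.patients)
        assert sum(len(pat.visits) for pat in log.patients) == 0

    def test_visit_conservation(self, small_params):
        log = run_scenario(small_params, ScenarioSpec("s", 0.3, 0.3), seed=11)
        hosp = comm = 0
        for pat in log.patients:
            if pat.plan is None:
                assert not pat.visits
                continue
            assert len(pat.visits) == pat.plan.planned_visits
            hosp += sum(v.setting == "hospital" for v in pat.visits)
            comm += sum(v.setting == "community" for v in pat.visits)
        assert hosp + comm == sum(len(pat.visits) for pat in log.patients)

    def test_visit_times_nondecreasing_and_after_arrival(self, small_params):
        log = run_scenario(small_params, ScenarioSpec("s", 0.5, 0.2), seed=13)
        for pat in log.patients:
            starts = [v.start_day for v in pat.visits]
            assert starts == sorted(starts)
            if starts:
                assert starts[0] >= pat.arrival_day

    def test_community_visits_use_no_doctor_time(self, small_params):
        p = small_params
        log = run_scenario(p, ScenarioSpec("c", 1.0, 0.0), seed=7, collect_trace=True)
        doctor_rows = [r for r in log.trace if r[0] == "service" and r[3] == "doctor"]
        # doctor time comes from diagnostics and *hospital* visits only
        n_exams = len([r for r in log.trace if r[4] == "consultant_exam"])
        n_hosp_visits = len([r for r in log.trace if r[0] == "visit" and r[4] == "hospital"])
        assert len(doctor_rows) == n_exams + n_hosp_visits

    def test_first_hospital_visit_seizes_exactly_one_doctor(self, small_params):
        log = run_scenario(small_params, BASE, seed=7, collect_trace=True)
        first_visits = [r for r in log.trace if r[0] == "visit" and r[3] == "first"]
        assert first_visits  # sanity
        pat = log.patients[[p.id for p in log.patients if p.plan][0]]
        reviews = [r for r in log.trace
                   if r[0] == "service" and r[3] == "doctor" and r[4] == "inr_review"
                   and r[2] == pat.id]
        assert len(reviews) == len(pat.visits)

    def test_staff_minutes_are_additive_over_services(self, small_params):
        # brute-force oracle: pool counters equal the sum of traced services
        log = run_scenario(small_params, ScenarioSpec("s", 0.4, 0.4), seed=19,
                           collect_trace=True)
        for pool in ("nurse", "doctor", "radiologist", "cs_nurse"):
            traced = sum(r[5] for r in log.trace if r[0] == "service" and r[3] == pool)
            assert log.pools[pool].busy_minutes == pytest.approx(traced)

    def test_halving_service_durations_halves_staff_hours(self, small_params):
        log1 = run_scenario(small_params, ScenarioSpec("s", 0.3, 0.3), seed=23)
        p2 = small_params.copy_deep()
        for k in p2.resources.service_minutes:
            p2.resources.service_minutes[k] /= 2.0
        log2 = run_scenario(p2, ScenarioSpec("s", 0.3, 0.3), seed=23)
        for pool in ("nurse", "doctor", "radiologist", "cs_nurse"):
            assert log2.pools[pool].busy_minutes == pytest.approx(
                log1.pools[pool].busy_minutes / 2.0)

    def test_negative_patients_have_no_plan(self, small_params):
        log = run_scenario(small_params, BASE, seed=29)
        for pat in log.patients:
            if pat.diagnosis == "negative-discharged":
                assert pat.plan is None
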