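"""Expectation oracle and calibration."""

from __future__ import annotations

import numpy as np
import pytest

from dvtflow import (CalibrationProblem, CalibrationTarget, calibrate,
                     expected_kpis, free_path)
from dvtflow.errors import ConfigurationError
from dvtflow.oracle import FreeParam, load_printed_tables, set_path
from dvtflow.reference import build_reference, skeleton_parameters
from dvtflow.scenarios import ScenarioSpec
from conftest import run_kpis

BASE = ScenarioSpec("base", 0.0, 0.0)


def _single_duration_params(ref_params, months=6):
    p = ref_params.copy_deep()
    for g in p.mix.duration_mix:
        p.mix.duration_mix[g] = {3: 0.0, 6: 0.0, 12: 0.0, months: 1.0}
    return p


class TestExpectedKpis:
    def test_baseline_visits_are_npos_times_mean_schedule(self, ref_params):
        p = _single_duration_params(ref_params, 6)
        e = expected_kpis(p, BASE)
        assert e.hospital_inr_visits == pytest.approx(e.n_positive * 14)
        assert e.community_visits == 0.0

    def test_all_noac_baseline_is_two_visits_each(self, ref_params):
        e = expected_kpis(ref_params, ScenarioSpec("noac", 0.0, 1.0))
        assert e.hospital_inr_visits == pytest.approx(e.n_positive * 2)

    def test_full_community_shift_keeps_retained_followups(self, ref_params):
        p = _single_duration_params(ref_params, 12)
        rho = p.pathway.hospital_retention
        e = expected_kpis(p, ScenarioSpec("cs", 1.0, 0.0))
        assert e.hospital_inr_visits == pytest.approx(e.n_positive * (1 + rho * 23))
        assert e.community_visits == pytest.approx(e.n_positive * (1 - rho) * 23)

    def test_cost_decomposition_identity(self, ref_params):
        e = expected_kpis(ref_params, ScenarioSpec("s", 0.3, 0.4))
        assert e.total_cost == pytest.approx(
            e.standard_care_cost + e.noac_cost + e.staff_cost)

    def test_usage_covers_the_active_cells(self, ref_params):
        e = expected_kpis(ref_params, ScenarioSpec("s", 0.5, 0.5))
        assert set(e.usage) == {"standard_hospital", "standard_community",
                                "NOAC_hospital", "NOAC_community"}
        n_total = sum(n for n, _ in e.usage.values())
        assert n_total == pytest.approx(e.n_positive)


class TestOracleMatchesSimulation:
    def test_replication_means_within_three_standard_errors(self, ref_params, rng):
        # random parameter/scenario draws at small scale, 25 replications:
        # the DES mean must sit within 3 SE of the closed form for the
        # headline KPIs (the central verification property)
        for draw in range(4):
            p = ref_params.copy_deep()
            p.demand.referral_rate = float(rng.uniform(0.3, 0.8))
            p.pathway.hospital_retention = float(rng.uniform(0.0, 0.6))
            p.demand.dvt_positive_fraction = float(rng.uniform(0.2, 0.5))
            s = ScenarioSpec(f"d{draw}", float(rng.uniform(0, 1)), float(rng.uniform(0, 1)))
            e = expected_kpis(p, s)
            reps = [run_kpis(p, s, seed=int(rng.integers(2**31))) for _ in range(25)]
            for kpi in ("hospital_inr_visits", "nurse_hours", "total_cost"):
                vals = np.array([r[kpi] for r in reps])
                se = vals.std(ddof=1) / np.sqrt(len(vals))
                assert abs(vals.mean() - e.get(kpi)) < 3 * se, (draw, kpi)


class TestCalibrate:
    def _problem(self, paths_bounds, targets):
        return CalibrationProblem([free_path(p, lo, hi) for p, lo, hi in paths_bounds],
                                  targets)

    def test_recovers_parameters_from_synthetic_targets(self, ref_params):
        truth = ref_params.copy_deep()
        truth.demand.referral_rate = 11.0
        truth.pathway.hospital_retention = 0.42
        truth.costs.followup_visit["hospital"] = 55.0
        scens = [ScenarioSpec("a", 0.2, 0.3), ScenarioSpec("b", 0.5, 0.1),
                 ScenarioSpec("c", 0.7, 0.6)]
        targets = [CalibrationTarget(s, k, expected_kpis(truth, s).get(k))
                   for s in scens
                   for k in ("hospital_inr_visits", "community_visits", "total_cost")]
        p0 = ref_params.copy_deep()  # start away from the truth
        result = calibrate(self._problem(
            [("demand.referral_rate", 4, 40),
             ("pathway.hospital_retention", 0.0, 0.9),
             ("costs.followup_visit.hospital", 10, 120)], targets), p0)
        assert result.params.demand.referral_rate == pytest.approx(11.0, rel=0.01)
        assert result.params.pathway.hospital_retention == pytest.approx(0.42, rel=0.01)
        assert result.params.costs.followup_visit["hospital"] == pytest.approx(55.0, rel=0.01)

    def test_zero_free_parameters_returns_input_with_residuals(self, ref_params):
        targets = [CalibrationTarget(BASE, "hospital_inr_visits", 50_000.0)]
        result = calibrate(CalibrationProblem([], targets), ref_params)
        assert result.params.model_dump() == ref_params.model_dump()
        assert len(result.residuals) == 1

    def test_underdetermined_problem_is_rejected(self, ref_params):
        targets = [CalibrationTarget(BASE, "hospital_inr_visits", 50_000.0)]
        with pytest.raises(ConfigurationError, match="identify"):
            calibrate(self._problem([("demand.referral_rate", 4, 40),
                                     ("pathway.hospital_retention", 0, 0.9)], targets),
                      ref_params)

    def test_confounded_parameters_trigger_a_rank_warning(self, ref_params):
        # radiologist minutes and radiologist rate enter every KPI only
        # through their product: unidentifiable as a pair
        targets = [CalibrationTarget(s, "staff_cost", expected_kpis(ref_params, s).staff_cost * 1.1)
                   for s in (BASE, ScenarioSpec("a", 0.2, 0.2), ScenarioSpec("b", 0.4, 0.4))]
        problem = self._problem(
            [("resources.service_minutes.ultrasound", 5, 40),
             ("costs.staff_hourly_rate.radiologist", 40, 150)], targets)
        with pytest.warns(UserWarning, match="confounded|rank-deficient"):
            result = calibrate(problem, ref_params)
        assert result.rank_warnings

    def test_set_path_reads_and_writes_nested_leaves(self, ref_params):
        apply, get = set_path("costs.drug_cost_per_day.NOAC")
        p = ref_params.copy_deep()
        apply(p, 1.23)
        assert get(p) == 1.23


@pytest.fixture(scope="module")
def rebuilt():
    with pytest.warns(UserWarning):  # bound-stuck columns are rank-deficient
        return build_reference()


class TestReferenceFit:

    def test_reference_fit_is_reproducible_from_the_printed_tables(self, rebuilt, ref_params):
        fitted, _ = rebuilt
        a, b = fitted.model_dump(), ref_params.model_dump()
        flat_a, flat_b = _flatten(a), _flatten(b)
        assert flat_a.keys() == flat_b.keys()
        for k in flat_a:
            va, vb = flat_a[k], flat_b[k]
            if isinstance(va, float) and isinstance(vb, float):
                assert va == pytest.approx(vb, rel=1e-4, abs=1e-9), k
            else:
                assert va == vb, k

    def test_baseline_row_within_the_five_percent_validation_band(self, rebuilt):
        _, result = rebuilt
        assert result.max_abs_residual("Baseline") <= 0.05

    def test_residual_report_covers_every_printed_target(self, rebuilt):
        _, result = rebuilt
        assert len(result.residuals) == len(load_printed_tables())

    def test_skeleton_differs_from_fit_only_in_calibrated_leaves(self):
        p0 = skeleton_parameters()
        assert p0.demand.base_population == 220_000  # printed values frozen
        assert p0.regimens["standard"].visits_by_duration[12] == 24


def _flatten(obj, prefix=""):
    out = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.update(_flatten(v, f"{prefix}{k}."))
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            out.update(_flatten(v, f"{prefix}{i}."))
    else:
        out[prefix[:-1]] = obj
    return out
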