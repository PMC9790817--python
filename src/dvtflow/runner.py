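"""Scenario-grid orchestration and reporting.

``run_grid`` runs every scenario with common random numbers: the same
per-replication seed stream is reused across scenarios, so two policy
points see identical referral streams and patient draws and differ only
in the policy thresholds -- between-scenario comparisons are sharpened
and each scenario's results are independent of grid order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .accounting import (SimulationResults, aggregate_replications,
                         compute_financial_kpis, compute_operational_kpis, kpi_dict)
from .errors import ConfigurationError
from .oracle import expected_kpis
from .params import INTERVENTIONS, ParameterSet
from .pathway import run_scenario
from .scenarios import ScenarioSpec, default_grid
from .star import VfMResult, score_interventions

__all__ = ["default_grid", "run_replications", "run_grid", "ResultsTable", "report"]


def params_hash(p: ParameterSet) -> str:
    return sha256(json.dumps(p.model_dump(), sort_keys=True, default=str)
                  .encode()).hexdigest()[:16]


def run_replications(p: ParameterSet, scenario: ScenarioSpec, n_reps: int,
                     seed: int | None = None,
                     seeds: list[np.random.SeedSequence] | None = None,
                     collect_usage: bool = True) -> tuple[SimulationResults, list[VfMResult]]:
    """Replicated run of one scenario; returns KPI statistics and mean VfM.

    ``seeds`` (one SeedSequence per replication) may be supplied directly
    to share streams across scenarios; otherwise they are spawned from
    ``seed``.
    """
    if seeds is None:
        if seed is None:
            raise ConfigurationError("either seed or seeds must be given")
        seeds = list(np.random.SeedSequence(seed).spawn(n_reps))
    per_rep = []
    usage_acc: dict[str, list[tuple[float, float]]] = {}
    for child in seeds[:n_reps]:
        log = run_scenario(p, scenario, child)
        op = compute_operational_kpis(log)
        fin, usage = compute_financial_kpis(log, p.costs, p.regimens)
        per_rep.append(kpi_dict(op, fin))
        if collect_usage:
            for u in usage:
                usage_acc.setdefault(u.intervention, []).append((u.n_patients, u.cost))
    results = aggregate_replications(scenario.label, per_rep)

    vfm: list[VfMResult] = []
    if collect_usage and usage_acc:
        from .accounting import InterventionUsage
        mean_usage = [
            InterventionUsage(lbl, float(np.mean([n for n, _ in vals])),
                              float(np.mean([c for _, c in vals])))
            for lbl, vals in sorted(usage_acc.items())
        ]
        vfm = score_interventions(p.star, mean_usage)
    return results, vfm


@dataclass
class ResultsTable:
    """One row per scenario, with reproduction metadata."""

    scenarios: list[ScenarioSpec]
    results: list[SimulationResults]
    vfm: list[list[VfMResult]]
    seed: int
    n_reps: int
    params_hash: str
    version: str = _version

    def operational_frame(self) -> pd.DataFrame:
        rows = []
        for s, r in zip(self.scenarios, self.results):
            rows.append({
                "scenario": s.label, "frac_cs": s.frac_cs, "frac_noac": s.frac_noac,
                "hospital_inr_visits": r.means["hospital_inr_visits"],
                "community_visits": r.means["community_visits"],
                "nurse_hours": r.means["nurse_hours"],
                "doctor_hours": r.means["doctor_hours"],
            })
        df = pd.DataFrame(rows)
        base = df.iloc[0]
        if base["frac_cs"] == 0 and base["frac_noac"] == 0:
            for col in ("hospital_inr_visits", "nurse_hours", "doctor_hours"):
                df[f"{col}_reduction_pct"] = [
                    percentage_reduction(base[col], x) for x in df[col]]
        return df

    def financial_frame(self) -> pd.DataFrame:
        rows = []
        for s, r in zip(self.scenarios, self.results):
            rows.append({
                "scenario": s.label, "frac_cs": s.frac_cs, "frac_noac": s.frac_noac,
                "standard_care_cost": r.means["standard_care_cost"],
                "noac_cost": r.means["noac_cost"],
                "staff_cost": r.means["staff_cost"],
                "total_cost": r.means["total_cost"],
            })
        df = pd.DataFrame(rows)
        base = df.iloc[0]
        if base["frac_cs"] == 0 and base["frac_noac"] == 0:
            df["total_cost_reduction_pct"] = [
                percentage_reduction(base["total_cost"], x) for x in df["total_cost"]]
        return df

    def vfm_frame(self) -> pd.DataFrame:
        rows = []
        for s, res in zip(self.scenarios, self.vfm):
            row = {"scenario": s.label, "frac_cs": s.frac_cs, "frac_noac": s.frac_noac}
            for r in res:
                row[r.intervention] = r.score
            for label in INTERVENTIONS:
                row.setdefault(label, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def percentage_reduction(baseline: float, value: float) -> int:
    """Integer percent reduction vs baseline, rounded as reported."""
    if baseline == 0:
        return 0
    return round((baseline - value) / baseline * 100.0)


def run_grid(p: ParameterSet, grid: list[ScenarioSpec] | None = None,
             n_reps: int = 30, seed: int = 20221226) -> ResultsTable:
    """Run every scenario under common random numbers."""
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    grid = grid if grid is not None else default_grid()
    labels = [s.label for s in grid]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("scenario labels must be unique within a grid")
    seeds = list(np.random.SeedSequence(seed).spawn(n_reps))
    results, vfm = [], []
    for s in grid:
        try:
            r, v = run_replications(p, s, n_reps, seeds=seeds)
        except Exception as exc:
            exc.args = (f"[{s.label}] {exc}",)
            raise
        results.append(r)
        vfm.append(v)
    return ResultsTable(grid, results, vfm, seed, n_reps, params_hash(p))


def expected_grid(p: ParameterSet, grid: list[ScenarioSpec] | None = None) -> pd.DataFrame:
    """Oracle (expected-value) analogue of run_grid, for quick what-ifs."""
    grid = grid if grid is not None else default_grid()
    rows = []
    for s in grid:
        e = expected_kpis(p, s)
        rows.append({"scenario": s.label, "frac_cs": s.frac_cs, "frac_noac": s.frac_noac,
                     "hospital_inr_visits": e.hospital_inr_visits,
                     "community_visits": e.community_visits,
                     "nurse_hours": e.nurse_hours, "doctor_hours": e.doctor_hours,
                     "standard_care_cost": e.standard_care_cost,
                     "noac_cost": e.noac_cost, "staff_cost": e.staff_cost,
                     "total_cost": e.total_cost})
    return pd.DataFrame(rows)


def report(rt: ResultsTable, fmt: str = "csv", directory: str | Path = ".") -> list[Path]:
    """Emit the operational/financial/VfM tables plus a JSON bundle."""
    if not rt.results:
        raise ConfigurationError("empty results table")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "csv":
        for name, df in (("operational", rt.operational_frame()),
                         ("financial", rt.financial_frame()),
                         ("vfm", rt.vfm_frame())):
            path = directory / f"results_{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
    elif fmt == "json":
        bundle = {
            "metadata": {"seed": rt.seed, "n_reps": rt.n_reps,
                         "params_hash": rt.params_hash, "version": rt.version},
            "scenarios": [
                {"label": s.label, "frac_cs": s.frac_cs, "frac_noac": s.frac_noac,
                 "means": r.means, "half_widths": r.half_widths,
                 "per_replication": r.per_rep,
                 "vfm": [v.__dict__ for v in vf]}
                for s, r, vf in zip(rt.scenarios, rt.results, rt.vfm)
            ],
        }
        path = directory / "results.json"
        path.write_text(json.dumps(bundle, indent=1))
        written.append(path)
    else:
        raise ConfigurationError(f"unknown report format '{fmt}' (use csv or json)")
    return written
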