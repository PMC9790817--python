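"""Model configuration: schema, loading, validation, serialization.

The configuration covers demand (a commissioning-group population referring
suspected-DVT patients), the case mix of confirmed patients, the two
anticoagulation regimens (warfarin-based standard care and NOAC), resource
capacities, unit costs, and the STAR benefit/feasibility inputs.

Two on-disk dialects are supported: canonical JSON, and a flat
``key,value,provenance`` CSV where keys are dotted paths into the schema.
Every leaf carries a provenance tag -- ``printed`` (stated in the source
tables/text), ``calibrated`` (fitted to the printed result tables by the
expectation oracle) or ``assumed`` (fixed from general knowledge of NHS DVT
services).

Field-range and cross-field invariants are deliberately checked by
:func:`validate_parameters` (a reporting operation that lists *every*
violated rule) rather than raised piecemeal at construction; pydantic
enforces structure and types only.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Literal

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import FormatError, ValidationFailure

#: Days per month used whenever a duration expressed in months is converted
#: to simulation days (12 * 30.4375 = 365.25, a Julian year).
DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: Treatment durations offered by the pathway, in months.
DURATIONS_MONTHS = (3, 6, 12)

GROUPS = ("provoked", "unprovoked", "recurrent")
REGIMENS = ("standard", "NOAC")
SETTINGS = ("hospital", "community")
RESOURCES = ("nurse", "doctor", "radiologist", "bed", "cs_nurse")

#: The four interventions scored by the STAR layer (regimen x setting).
INTERVENTIONS = (
    "NOAC_community",
    "standard_community",
    "NOAC_hospital",
    "standard_hospital",
)

#: Diagnostic sequence: activity name -> resource that delivers it.
#: Patients go through all five steps in order, in hospital, before the
#: positive/negative decision.
DIAGNOSTIC_STEPS = (
    ("history", "nurse"),
    ("consultant_exam", "doctor"),
    ("wells_score", "nurse"),
    ("d_dimer", "nurse"),
    ("ultrasound", "radiologist"),
)

_STRICT = ConfigDict(extra="forbid", validate_assignment=False)


class DemandParams(BaseModel):
    """Referral demand over the simulated horizon."""

    model_config = _STRICT

    base_population: float
    referral_rate: float  # suspected-DVT referrals per 1,000 population per year
    dvt_positive_fraction: float  # P(confirmed DVT | referral)
    annual_growth: float  # fractional growth of the referral rate per year
    horizon_years: int
    #: Documentation metadata only: published UK DVT prevalence per 100,000.
    #: Used by validate_parameters to warn (not error) when the configured
    #: demand volume is far from what prevalence alone would suggest.
    prevalence_per_100k: float | None = None


class GroupMix(BaseModel):
    """Case mix of confirmed DVT patients.

    ``duration_mix[group][months]`` is the probability that a patient of
    that aetiological group is put on a 3-, 6- or 12-month anticoagulation
    course.
    """

    model_config = _STRICT

    group_fractions: dict[str, float]
    duration_mix: dict[str, dict[int, float]]

    def aggregate_duration_dist(self) -> dict[int, float]:
        """Marginal duration distribution over all groups."""
        agg = {d: 0.0 for d in DURATIONS_MONTHS}
        for g, fg in self.group_fractions.items():
            for d, p in self.duration_mix[g].items():
                agg[d] += fg * p
        return agg


class DrugPhase(BaseModel):
    """One phase of a regimen's drug schedule.

    ``length_days`` is a fixed number of days or ``"remainder"`` (the rest
    of the treatment duration); ``drug`` keys into
    :attr:`CostSchedule.drug_cost_per_day`.
    """

    model_config = _STRICT

    drug: str
    length_days: int | Literal["remainder"]


class RegimenDef(BaseModel):
    model_config = _STRICT

    name: Literal["standard", "NOAC"]
    visits_by_duration: dict[int, int]  # months -> INR clinic visit count
    drug_phases: list[DrugPhase]


class ResourceParams(BaseModel):
    """Staffing and per-activity service durations.

    ``headcount`` and ``dvt_allocation`` together give each pool's
    effective capacity; ``service_minutes`` holds the hands-on duration of
    every pathway activity.
    """

    model_config = _STRICT

    headcount: dict[str, float]
    dvt_allocation: dict[str, float]  # fraction of time allocated to DVT work
    service_minutes: dict[str, float]


class CostSchedule(BaseModel):
    model_config = _STRICT

    first_visit: dict[str, float]  # setting -> GBP
    followup_visit: dict[str, float]  # setting -> GBP
    drug_cost_per_day: dict[str, float]  # drug -> GBP per day/tablet/injection
    staff_hourly_rate: dict[str, float]  # resource -> GBP per hour


class InterventionScore(BaseModel):
    model_config = _STRICT

    benefit: float  # elicited per-patient health benefit (dimensionless)
    feasibility: float  # P(the benefit is realised)


class StarParams(BaseModel):
    model_config = _STRICT

    interventions: dict[str, InterventionScore]
    vfm_scale: float  # multiplier applied to the benefit-per-GBP ratio


class PathwayParams(BaseModel):
    """Routing probabilities that are not part of demand or case mix."""

    model_config = _STRICT

    referral_source_mix: dict[str, float]  # GP / A&E / outpatient / community
    #: Probability that a follow-up of a community-managed patient is still
    #: delivered at the hospital anticoagulation clinic (INR blood checks
    #: that community services do not fully substitute). Calibrated.
    hospital_retention: float


class ParameterSet(BaseModel):
    """The full model configuration."""

    model_config = _STRICT

    demand: DemandParams
    mix: GroupMix
    regimens: dict[str, RegimenDef]
    resources: ResourceParams
    costs: CostSchedule
    star: StarParams
    pathway: PathwayParams
    #: dotted path -> {printed, calibrated, assumed}
    provenance: dict[str, str] = {}

    def copy_deep(self) -> "ParameterSet":
        return self.model_copy(deep=True)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Finding:
    path: str
    message: str
    severity: str  # "error" | "warning"


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    def add(self, path: str, message: str, severity: str = "error") -> None:
        self.findings.append(Finding(path, message, severity))

    def __bool__(self) -> bool:  # truthy iff clean of errors
        return not self.errors


def _check_dist(report: ValidationReport, path: str, dist: dict, tol: float = 1e-9) -> None:
    total = sum(dist.values())
    if any(v < 0 for v in dist.values()):
        report.add(path, "contains negative probabilities")
    elif not math.isclose(total, 1.0, abs_tol=tol):
        report.add(path, f"probabilities sum {total:.10g}, expected 1")


def validate_parameters(p: ParameterSet) -> ValidationReport:
    """Check every declared invariant; return a report of all findings.

    Zero error findings means the set is usable. Warnings flag
    configurations that are legal but suspicious, notably a demand volume
    inconsistent by more than 20% with the documented prevalence metadata.
    """
    r = ValidationReport()
    d = p.demand
    if d.base_population <= 0:
        r.add("demand.base_population", "must be > 0")
    if d.referral_rate < 0:
        r.add("demand.referral_rate", "must be >= 0")
    if not 0 <= d.dvt_positive_fraction <= 1:
        r.add("demand.dvt_positive_fraction", "must be in [0, 1]")
    if d.annual_growth < -1:
        r.add("demand.annual_growth", "must be >= -1")
    if d.horizon_years < 1:
        r.add("demand.horizon_years", "must be >= 1")

    _check_dist(r, "mix.group_fractions", p.mix.group_fractions)
    if set(p.mix.group_fractions) != set(GROUPS):
        r.add("mix.group_fractions", f"keys must be exactly {set(GROUPS)}")
    for g in p.mix.duration_mix:
        _check_dist(r, f"mix.duration_mix.{g}", p.mix.duration_mix[g])
        if set(p.mix.duration_mix[g]) != set(DURATIONS_MONTHS):
            r.add(f"mix.duration_mix.{g}", f"durations must be exactly {set(DURATIONS_MONTHS)}")

    if set(p.regimens) != set(REGIMENS):
        r.add("regimens", f"keys must be exactly {set(REGIMENS)}")
    for name, reg in p.regimens.items():
        for dur, v in reg.visits_by_duration.items():
            if v < 1:
                r.add(f"regimens.{name}.visits_by_duration.{dur}", "visit count must be >= 1")
        remainder_idx = [i for i, ph in enumerate(reg.drug_phases) if ph.length_days == "remainder"]
        if len(remainder_idx) > 1:
            r.add(f"regimens.{name}.drug_phases", '"remainder" may appear at most once')
        elif remainder_idx and remainder_idx[0] != len(reg.drug_phases) - 1:
            r.add(f"regimens.{name}.drug_phases", '"remainder" phase must be last')
        for i, ph in enumerate(reg.drug_phases):
            if isinstance(ph.length_days, int) and ph.length_days < 0:
                r.add(f"regimens.{name}.drug_phases.{i}", "phase length must be >= 0")

    res = p.resources
    for k, v in res.headcount.items():
        if v < 0:
            r.add(f"resources.headcount.{k}", "must be >= 0")
    for k, v in res.dvt_allocation.items():
        if not 0 <= v <= 1:
            r.add(f"resources.dvt_allocation.{k}", "must be in [0, 1]")
    for k, v in res.service_minutes.items():
        if v <= 0:
            r.add(f"resources.service_minutes.{k}", "must be > 0")
    for act, _pool in DIAGNOSTIC_STEPS:
        if act not in res.service_minutes:
            r.add(f"resources.service_minutes.{act}", "missing duration for diagnostic step")
    for act in ("hospital_visit_nurse", "hospital_visit_doctor", "community_visit_nurse",
                "bed_occupancy_first_visit"):
        if act not in res.service_minutes:
            r.add(f"resources.service_minutes.{act}", "missing duration for visit activity")

    for section, dct in (("first_visit", p.costs.first_visit),
                         ("followup_visit", p.costs.followup_visit),
                         ("drug_cost_per_day", p.costs.drug_cost_per_day),
                         ("staff_hourly_rate", p.costs.staff_hourly_rate)):
        for k, v in dct.items():
            if v < 0:
                r.add(f"costs.{section}.{k}", "costs must be >= 0")

    for name, sc in p.star.interventions.items():
        if sc.benefit < 0:
            r.add(f"star.interventions.{name}.benefit", "must be >= 0")
        if not 0 <= sc.feasibility <= 1:
            r.add(f"star.interventions.{name}.feasibility", "must be in [0, 1]")
    if p.star.vfm_scale <= 0:
        r.add("star.vfm_scale", "must be > 0")

    _check_dist(r, "pathway.referral_source_mix", p.pathway.referral_source_mix)
    if not 0 <= p.pathway.hospital_retention <= 1:
        r.add("pathway.hospital_retention", "must be in [0, 1]")

    # prevalence consistency: warning only
    if d.prevalence_per_100k is not None and d.referral_rate > 0:
        configured = d.base_population * d.referral_rate / 1000.0 * d.dvt_positive_fraction
        documented = d.base_population * d.prevalence_per_100k / 100_000.0
        if documented > 0 and abs(configured - documented) / documented > 0.20:
            r.add(
                "demand",
                f"configured DVT-positive volume {configured:.0f}/yr differs from "
                f"documented prevalence volume {documented:.0f}/yr by more than 20%",
                severity="warning",
            )
    return r


# ---------------------------------------------------------------------------
# loading / saving


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.update(_flatten(v, f"{prefix}{k}."))
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            out.update(_flatten(v, f"{prefix}{i}."))
    else:
        out[prefix[:-1]] = obj
    return out


def _unflatten(flat: dict[str, str]) -> dict:
    root: dict = {}
    for key, raw in flat.items():
        parts = key.split(".")
        node = root
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = _parse_scalar(raw)
    return _listify(root)


def _listify(node: Any) -> Any:
    """Turn {0: .., 1: ..}-shaped dicts (from flattened lists) back into lists."""
    if not isinstance(node, dict):
        return node
    node = {k: _listify(v) for k, v in node.items()}
    keys = list(node)
    if keys and all(isinstance(k, str) and k.isdigit() for k in keys):
        idx = sorted(int(k) for k in keys)
        if idx == list(range(len(idx))):
            return [node[str(i)] for i in idx]
    return node


def _parse_scalar(raw: Any) -> Any:
    if not isinstance(raw, str):
        return raw
    s = raw.strip()
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s.lower() in ("true", "false"):
        return s.lower() == "true"
    if s.lower() in ("none", "null", ""):
        return None
    return s


def _format_pydantic_error(exc: ValidationError) -> ValidationFailure:
    report = ValidationReport()
    for err in exc.errors():
        path = ".".join(str(x) for x in err["loc"])
        report.add(path or "<root>", err["msg"])
    return ValidationFailure(report)


def load_parameters(source: str | Path) -> ParameterSet:
    """Load and validate a configuration document (JSON or key-value CSV).

    Unknown keys are rejected (reported by path, never silently dropped);
    any invariant violation raises :class:`ValidationFailure` carrying the
    full report.
    """
    path = Path(source)
    if not path.exists():
        raise FormatError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".csv":
        flat: dict[str, str] = {}
        prov: dict[str, str] = {}
        for lineno, row in enumerate(csv.reader(text.splitlines()), start=1):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "key" and lineno == 1:
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected key,value[,provenance]")
            if row[0].startswith("provenance."):
                # section-level tags: the remainder of the key is stored verbatim
                prov[row[0][len("provenance."):]] = row[1]
                continue
            flat[row[0]] = row[1]
            if len(row) > 2 and row[2]:
                prov[row[0]] = row[2]
        data = _unflatten(flat)
        if prov:
            data["provenance"] = prov
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}:{exc.lineno}: {exc.msg}") from exc
    try:
        p = ParameterSet.model_validate(data)
    except ValidationError as exc:
        raise _format_pydantic_error(exc) from exc
    report = validate_parameters(p)
    if not report:
        raise ValidationFailure(report)
    return p


def save_parameters(p: ParameterSet, dest: str | Path) -> None:
    """Serialize losslessly; dialect chosen from the file suffix."""
    path = Path(dest)
    data = p.model_dump()
    if path.suffix.lower() == ".csv":
        prov = data.pop("provenance", {})
        flat = _flatten(data)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["key", "value", "provenance"])
            for k, v in flat.items():
                w.writerow([k, v, prov.get(k, "")])
            for k, tag in prov.items():  # tags on non-leaf paths
                if k not in flat:
                    w.writerow([f"provenance.{k}", tag, ""])
    else:
        path.write_text(json.dumps(data, indent=1, sort_keys=False) + "\n")


_REFERENCE_FILE = "reference_parameters.json"


def reference_parameters() -> ParameterSet:
    """The packaged reference configuration.

    Printed components (visit schedules 9/14/24 and 2, the 8-day LMWH
    phase, 1%/yr growth, the 5-year horizon, the 220,000 base population)
    are taken from the source tables; unprinted components are calibrated
    against the baseline and scenario result tables by
    :func:`dvtflow.oracle.calibrate` (tags in ``provenance``).
    """
    with resources.files("dvtflow.data").joinpath(_REFERENCE_FILE).open() as fh:
        data = json.load(fh)
    return ParameterSet.model_validate(data)
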