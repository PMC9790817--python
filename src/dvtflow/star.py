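"""STAR value-for-money scoring of the four interventions.

STAR (Socio-Technical Allocation of Resources) scores an intervention by
the expected health benefit it delivers per unit expenditure. For each
regimen x setting cohort the simulation supplies the number of patients
and the cohort's expenditure; stakeholder-elicited inputs supply the
per-patient benefit score and the feasibility (the probability the
benefit is realised):

    EHB   = n_patients * benefit * feasibility
    score = vfm_scale * EHB / cost

The benefit scores are treated as scenario-independent per intervention;
all variation across scenarios flows from the simulated patient counts
and costs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .accounting import InterventionUsage
from .errors import ConfigurationError
from .params import StarParams


@dataclass(frozen=True)
class VfMInputs:
    intervention: str
    n_patients: float
    benefit: float  # elicited per-patient health-benefit score
    feasibility: float
    cost: float  # GBP


@dataclass(frozen=True)
class VfMResult:
    intervention: str
    n_patients: float
    expected_health_benefit: float
    cost: float
    score: float


def expected_health_benefit(inputs: VfMInputs) -> float:
    """Total expected benefit of the cohort: n * per-patient benefit * feasibility."""
    return inputs.n_patients * inputs.benefit * inputs.feasibility


def value_for_money(ehb: float, cost: float, scale: float = 1.0) -> float:
    """Benefit-per-expenditure score, scaled for readability."""
    if cost < 0:
        raise ConfigurationError("intervention cost must be >= 0")
    if cost == 0:
        if ehb > 0:
            raise ConfigurationError("value-for-money undefined: positive benefit at zero cost")
        warnings.warn("zero benefit at zero cost: score defined as 0", stacklevel=2)
        return 0.0
    return scale * ehb / cost


def score_interventions(star: StarParams,
                        usage: list[InterventionUsage]) -> list[VfMResult]:
    """Score each simulated cohort with the configured STAR inputs."""
    results = []
    for u in usage:
        try:
            sc = star.interventions[u.intervention]
        except KeyError:
            raise ConfigurationError(f"no STAR inputs for intervention '{u.intervention}'") from None
        inp = VfMInputs(u.intervention, u.n_patients, sc.benefit, sc.feasibility, u.cost)
        ehb = expected_health_benefit(inp)
        score = value_for_money(ehb, u.cost, star.vfm_scale) if (ehb > 0 or u.cost > 0) else 0.0
        results.append(VfMResult(u.intervention, u.n_patients, ehb, u.cost, score))
    return results


def rank_interventions(results: list[VfMResult]) -> list[VfMResult]:
    """Descending by score; ties broken by lower cost, then label.

    The ordering is total and invariant to the input permutation.
    """
    if not results:
        raise ConfigurationError("nothing to rank")
    return sorted(results, key=lambda r: (-r.score, r.cost, r.intervention))
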