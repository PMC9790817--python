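"""Policy scenarios: community-services shift x NOAC uptake."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class ScenarioSpec:
    """One policy point.

    ``frac_cs``: fraction of confirmed patients managed in community
    services; ``frac_noac``: fraction treated with NOAC. The two splits are
    applied independently, so all four regimen x setting cells occur.
    """

    label: str
    frac_cs: float
    frac_noac: float

    def __post_init__(self) -> None:
        for name in ("frac_cs", "frac_noac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"scenario '{self.label}': {name}={v} outside [0, 1]")


BASELINE = ScenarioSpec("Baseline", 0.0, 0.0)

_LEVELS = (0.10, 0.20, 0.40, 0.50)


def default_grid() -> list[ScenarioSpec]:
    """Baseline plus the 4x4 policy grid over {10, 20, 40, 50}% each way.

    Scenario numbering follows the published list: scenarios 1-4 hold the
    community shift at 10% while NOAC uptake runs through 10/20/40/50%,
    scenarios 5-8 use a 20% shift, and so on.
    """
    grid = [BASELINE]
    k = 1
    for cs in _LEVELS:
        for noac in _LEVELS:
            grid.append(ScenarioSpec(f"Scenario {k}", cs, noac))
            k += 1
    return grid
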