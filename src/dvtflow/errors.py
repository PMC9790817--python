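"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line interface: configuration and
validation problems are user errors (exit 2); internal consistency failures
of the event engine are bugs and fail loudly (exit 3).
"""

from __future__ import annotations


class DvtFlowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DvtFlowError):
    """A parameter set is structurally unusable for the requested run.

    Examples: a reachable activity with no resourced pool, a missing
    service duration, a missing unit cost.
    """


class FormatError(ConfigurationError):
    """A configuration document could not be parsed."""


class ValidationFailure(ConfigurationError):
    """A parameter set violates one or more declared invariants.

    Carries the full validation report so every violated rule is surfaced,
    not only the first.
    """

    def __init__(self, report) -> None:
        self.report = report
        lines = "; ".join(f"{f.path}: {f.message}" for f in report.errors)
        super().__init__(f"{len(report.errors)} validation error(s): {lines}")


class ConsistencyError(DvtFlowError):
    """Internal invariant of the event engine broken (e.g. an action
    scheduling an event in the past, or an unterminated resource seize)."""


class DomainError(DvtFlowError):
    """A lookup outside a regimen's defined domain (e.g. unknown treatment
    duration)."""
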