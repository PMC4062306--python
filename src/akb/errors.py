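"""Exception hierarchy for the abnormality knowledge base."""

from __future__ import annotations


class AkbError(Exception):
    """Base class for all package errors."""


class ValidationError(AkbError):
    """A descriptor or bundle violates a structural invariant.

    Carries the list of violated invariants so callers can report all
    problems at once instead of failing on the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class UnknownClassError(AkbError, KeyError):
    """A class id does not resolve in the taxonomy."""


class CycleError(AkbError):
    """An is-a or causal graph would become cyclic."""

    def __init__(self, message, cycle=None):
        self.cycle = list(cycle) if cycle else []
        super().__init__(message)


class RuleConfigError(AkbError):
    """A decomposition rule set is ambiguous or malformed."""


class UnitMismatchError(AkbError):
    """Quantitative value and threshold specification disagree on units."""


class NoThresholdError(AkbError):
    """No threshold specification targets the given object/attribute."""


class DegreeBandError(AkbError):
    """Grading was requested but the threshold spec carries no degree bands."""


class BundleError(AkbError):
    """A model bundle failed schema validation; message carries the path."""


class InfeasibleConfigError(AkbError):
    """A synthetic-generation config cannot be satisfied."""
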