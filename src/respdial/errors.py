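"""Exception hierarchy.

Exit-code mapping used by the CLI: validation errors -> 2, convergence /
stability errors -> 3, I/O and fixture-integrity errors -> 4.
"""


class RespdialError(Exception):
    """Base class for all package errors."""


class ValidationError(RespdialError, ValueError):
    """An input violated a precondition (negative concentration, bad range...)."""


class DomainError(ValidationError):
    """An argument lies outside the mathematical domain of an operation."""


class DesignError(RespdialError):
    """The dialysate design constraints are infeasible."""

    def __init__(self, message: str, ion: str | None = None):
        super().__init__(message)
        self.ion = ion


class ConvergenceError(RespdialError):
    """A root-finder or fixed-point sweep failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StabilityError(ConvergenceError):
    """A simulated concentration went negative; discretisation too coarse."""


class PairingError(ValidationError):
    """Pre/post blood-gas records could not be matched."""


class InsufficientReplicatesError(ValidationError):
    """Fewer replicates than the statistical operation requires."""


class FixtureIntegrityError(RespdialError, IOError):
    """A packaged data fixture failed its checksum."""
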