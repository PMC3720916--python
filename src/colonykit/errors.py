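"""Exception hierarchy used across colonykit."""


class ColonyKitError(Exception):
    """Base class for all colonykit errors."""


class DomainError(ColonyKitError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class NoRootError(DomainError):
    """A requested root does not exist (e.g. f2 above the feasible maximum)."""


class InsufficientDataError(ColonyKitError, ValueError):
    """Too few data points to carry out a fit or band computation."""


class IncomparableFitsError(ColonyKitError, ValueError):
    """Model-selection attempted across fits on different observation sets."""


class OptimizationError(ColonyKitError, RuntimeError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class FormatError(ColonyKitError, ValueError):
    """A table or configuration file violates the expected schema."""
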