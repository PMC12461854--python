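"""Exception hierarchy shared across the package."""


class ClimsensError(Exception):
    """Base class for all package errors."""


class ConfigError(ClimsensError):
    """A study configuration violates the schema or an invariant."""


class IncompleteEnvironmentError(ClimsensError):
    """An environment lacks a value for a driver a model needs."""


class DomainError(ClimsensError):
    """An individual state falls outside a model's applicable domain."""


class UndefinedSensitivityError(ClimsensError):
    """The focal driver has zero range or zero SD (Eq-style denominator is 0)."""


class InviablePopulationError(ClimsensError):
    """All simulation replicates went extinct before burn-in ended."""


class NonConvergenceError(ClimsensError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class VitalRateSkip(ClimsensError):
    """Signal that a vital rate cannot be perturbed for the requested driver
    (the rate does not contain it); callers running grids catch and skip."""
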