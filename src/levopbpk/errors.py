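"""Exception hierarchy for levopbpk.

All package-specific failures derive from :class:`LevoPBPKError` so callers can
catch a single base. Validation failures (bad configs, broken invariants) are
kept distinct from runtime failures (solver, optimizer) because the CLI maps
them to different exit codes.
"""


class LevoPBPKError(Exception):
    """Base class for all levopbpk errors."""


class ValidationError(LevoPBPKError):
    """A config, parameter set or input table violates an invariant."""


class UnsupportedSpeciesError(ValidationError):
    """Requested species has no packaged physiology."""


class DuplicateCompartmentError(ValidationError):
    """Attempt to create a compartment that already exists."""


class ConfigurationError(ValidationError):
    """Model assembly failed (missing partition entry, unbalanced flows...)."""


class InputError(ValidationError):
    """Malformed numeric input (unsorted times, empty schedule...)."""


class DomainError(LevoPBPKError):
    """A quantity is outside the mathematical domain of an operation."""


class WindowRangeError(LevoPBPKError):
    """Requested time window lies outside the simulated span."""


class IntegrationError(LevoPBPKError):
    """ODE solver failed to meet its tolerance contract."""


class ConvergenceError(LevoPBPKError):
    """Optimizer failed to bracket or reach a minimum."""


class DegenerateDataError(ConvergenceError):
    """Observed data carry no information for the requested fit."""
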