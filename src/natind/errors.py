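"""Exception hierarchy for natind."""


class NatindError(Exception):
    """Base class for all natind errors."""


class ParameterError(NatindError, ValueError):
    """A parameter violates its documented domain."""


class GenerationError(NatindError):
    """A network generator failed (e.g. no connected draw within the redraw budget)."""


class EdgeListError(NatindError, ValueError):
    """A malformed edge-list file; the message names the offending line."""


class DegenerateGeometryError(NatindError):
    """Two connected masses are coincident, so the force direction is undefined."""


class IntegrationError(NatindError):
    """The state integration produced non-finite values (step size too large)."""


class AssayError(NatindError):
    """An assay's preconditions are not met (too few records, zero variance, ...)."""


class ContractError(NatindError):
    """An operation was called on an object that violates its contract."""


class ConfigError(NatindError, ValueError):
    """A configuration file contains unknown keys or ill-typed values."""
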