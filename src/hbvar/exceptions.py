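"""Exception hierarchy shared across the package."""


class HbvarError(Exception):
    """Base class for all package errors."""


class ConfigError(HbvarError, ValueError):
    """A configuration object violates its invariants; message names the field."""


class DataError(HbvarError, ValueError):
    """An input table violates a precondition; message names the offending row."""


class DomainError(HbvarError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class EstimationError(HbvarError, RuntimeError):
    """An iterative estimator failed to converge; message carries the trace."""


class BinningError(HbvarError, ValueError):
    """A value falls outside the configured bin edges."""


class SpecificationError(HbvarError, ValueError):
    """A subgroup specification refers to an unknown variable or is malformed."""


class PipelineError(HbvarError, RuntimeError):
    """An end-to-end run aborted; message names the failing stage."""
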