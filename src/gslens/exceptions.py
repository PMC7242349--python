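"""Exception hierarchy shared across the package."""


class GslensError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GslensError, ValueError):
    """A configuration value is outside its admissible range."""


class InputError(GslensError, ValueError):
    """Input data violates a precondition (missing values, wrong length, ...)."""


class DegenerateInputError(InputError):
    """Input is formally valid but degenerate (constant response, all-monomorphic markers)."""


class FormatError(GslensError, ValueError):
    """A file could not be parsed; the message names the offending row/column."""


class ContractError(GslensError, ValueError):
    """Two objects that must share structure (e.g. a lambda grid) do not."""


class NumericalError(GslensError, RuntimeError):
    """A numerical routine failed to converge or produced an invalid result."""
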