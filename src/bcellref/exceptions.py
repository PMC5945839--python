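"""Exception hierarchy.

Validation problems (bad configuration, malformed tables) are distinguished
from computation problems (non-convergence, insufficient data) so that the
command-line layer can map them onto distinct exit codes.
"""


class BCellRefError(Exception):
    """Base class for all package errors."""


class ValidationError(BCellRefError):
    """Input data violates a structural contract (bad column, bad value)."""


class ConfigError(ValidationError):
    """A configuration field is invalid; the message names the field."""


class InsufficientDataError(BCellRefError):
    """Too few observations (or too few distinct ages) to fit the model."""


class ConvergenceError(BCellRefError):
    """A fit did not converge and a downstream stage refused to use it."""


class RangeError(BCellRefError):
    """An age outside the supported reference domain with extrapolation off."""


class MissingReferenceError(BCellRefError):
    """No reference available for a measured subset/measure pair."""
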