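"""Exception hierarchy for the rtwave pipeline.

All exceptions derive from :class:`RTWaveError` so callers can catch the
package's failures with a single handler; each subclass also derives from
``ValueError`` so bare library-style handling keeps working.
"""


class RTWaveError(ValueError):
    """Base class for all rtwave errors."""


class InvalidParameterError(RTWaveError):
    """A generator or model parameter violates its invariants."""


class SchemaError(RTWaveError):
    """An input table is missing required columns or is otherwise malformed."""


class InputError(RTWaveError):
    """An input file or table is unusable (e.g. empty after validation)."""


class ConfigError(RTWaveError):
    """A run configuration is internally inconsistent."""


class DegenerateInputError(RTWaveError):
    """An operation received input for which its result is undefined
    (constant vectors, zero variance, fewer than two values...)."""


class InsufficientArmError(RTWaveError):
    """A profile arm has too few points to fit a cubic smoothing spline."""
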