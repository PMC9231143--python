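"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class MMGForceError(Exception):
    """Base class for all package errors."""


class ConfigError(MMGForceError):
    """Invalid configuration or parameter value."""


class DataError(MMGForceError):
    """Input data violates a precondition (shape, length, content)."""


class NumericalError(MMGForceError):
    """A computation could not produce a valid numerical result."""


class NoStableSegmentError(DataError):
    """No window of the force trace satisfies the stability rule."""


class FeatureError(NumericalError):
    """A feature is undefined for the given window (e.g. constant input)."""


class NotFittedError(MMGForceError):
    """A scaler or model was used before being fitted."""
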