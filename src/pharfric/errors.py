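"""Exception hierarchy.

Everything raised on bad user input derives from both :class:`PharfricError`
and a fitting builtin, so callers may catch either.
"""


class PharfricError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PharfricError, ValueError):
    """Unreadable or unsupported file format."""


class EmptyInputError(PharfricError, ValueError):
    """A signal or dataset with no usable content."""


class InvalidFramingError(PharfricError, ValueError):
    """Requested more frames than there are samples."""


class ConfigError(PharfricError, ValueError):
    """Inconsistent or out-of-range configuration value."""


class InsufficientDataError(PharfricError, ValueError):
    """Not enough points/segments for the requested computation."""


class InvalidCutoffError(PharfricError, ValueError):
    """Cut-off frequency outside (0, fs/2)."""


class InvalidPairError(PharfricError, ValueError):
    """Paired sequences with mismatched lengths."""


class DegenerateSpectrumError(PharfricError, ValueError):
    """Fewer than two usable octave bands for regression."""


class DegenerateTrainingError(PharfricError, ValueError):
    """Training data containing a single class."""


class SchemaError(PharfricError, ValueError):
    """Manifest/feature table missing required columns or holding bad codes."""


class ShapeError(PharfricError, ValueError):
    """Feature dimensionality does not match the fitted model."""
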