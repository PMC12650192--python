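"""Exception hierarchy for breathfit.

All package errors derive from :class:`BreathfitError` so callers can catch
pipeline failures with a single handler while still discriminating the cause.
"""


class BreathfitError(Exception):
    """Base class for all breathfit errors."""


class SchemaError(BreathfitError):
    """A file is missing a required column or maps columns inconsistently."""


class FormatError(BreathfitError):
    """A file violates a structural contract (e.g. non-uniform time base)."""


class DataError(BreathfitError):
    """Cell-level data problems: NaNs, gaps, out-of-range values."""


class VocabularyError(BreathfitError):
    """A label token outside the closed {fit, poor_fit, other} vocabulary."""


class IntervalError(BreathfitError):
    """A degenerate or inverted time interval."""


class ConsistencyError(BreathfitError):
    """Mutually inconsistent inputs (e.g. overlapping label segments)."""


class ConfigError(BreathfitError):
    """Invalid configuration value or combination."""


class ParameterError(BreathfitError):
    """A numeric parameter outside its admissible range."""


class LengthError(BreathfitError):
    """A series too short (or wrong-length) for the requested operation."""


class DegenerateSignalError(BreathfitError):
    """Zero-variance or otherwise degenerate signal where statistics are undefined."""


class EmptyTableError(BreathfitError):
    """A feature table with no rows after filtering."""


class TrainingError(BreathfitError):
    """Classifier training cannot proceed (e.g. single-class targets)."""
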