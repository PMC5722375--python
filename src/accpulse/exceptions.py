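"""Exception hierarchy for accpulse.

All package errors derive from :class:`AccPulseError` so callers can catch
one base class at pipeline boundaries.
"""


class AccPulseError(Exception):
    """Base class for all accpulse errors."""


class FormatError(AccPulseError):
    """A file does not have the expected layout (e.g. a missing column)."""


class TimingError(AccPulseError):
    """A waveform time base is not uniform within tolerance."""


class EmptyInputError(AccPulseError):
    """An input file or series contains no data."""


class AnnotationError(AccPulseError):
    """A label value cannot be mapped onto the known classes."""


class ConfigurationError(AccPulseError):
    """A parameter violates a precondition (e.g. cutoff above Nyquist)."""


class LengthError(AccPulseError):
    """A signal is too short for the requested operation."""


class ShapeError(AccPulseError):
    """Two series that must have equal length do not."""


class DegenerateInputError(AccPulseError):
    """The operation is undefined on this input (e.g. an all-zero signal)."""


class DataError(AccPulseError):
    """Samples are non-finite or otherwise unusable."""
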