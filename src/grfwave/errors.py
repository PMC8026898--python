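"""Exception hierarchy for the GRF waveform pipeline.

All package errors derive from :class:`GRFError` so callers can catch one
base class; the CLI maps :class:`ConfigError` to exit code 2 and every
other :class:`GRFError` to exit code 3.
"""


class GRFError(Exception):
    """Base class for all errors raised by grfwave."""


class FormatError(GRFError):
    """Input file does not have the expected layout (missing columns, bad header)."""


class DataError(GRFError):
    """Input data violate an invariant (non-monotone time, non-finite forces)."""


class ParameterError(GRFError):
    """A parameter is outside its valid range (e.g. cutoff above Nyquist)."""


class SegmentationError(GRFError):
    """A stance segment is unusable (too short, out of recording bounds)."""


class GroupingError(GRFError):
    """Curves that must share subject/condition/channel do not."""


class NoImpactPeakError(GRFError):
    """No early impact peak could be located in a vertical stance curve."""


class InsufficientDataError(GRFError):
    """Not enough observations for the requested statistical test."""


class ConfigError(GRFError):
    """Pipeline configuration is invalid (unknown keys, bad values)."""
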