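"""Exception hierarchy for the correction pipeline.

All package exceptions derive from :class:`SaxsredError` so callers can
catch everything the pipeline may raise with one clause; the subclasses
also derive from the closest builtin (``ValueError``/``RuntimeError``) so
generic handling keeps working.
"""


class SaxsredError(Exception):
    """Base class for all saxsred errors."""


class ShapeError(SaxsredError, ValueError):
    """Array dimensions of two operands do not match."""


class UnitsStateError(SaxsredError, ValueError):
    """Frames are in incompatible units states for the requested operation."""


class SequenceError(SaxsredError, RuntimeError):
    """A correction step was requested out of its admissible order."""


class SaturationError(SaxsredError, ValueError):
    """Detected count rate too close to the deadtime limit to correct."""


class MetadataError(SaxsredError, ValueError):
    """Required measurement metadata is missing or inconsistent."""


class FormatError(SaxsredError, ValueError):
    """An input file violates the expected on-disk format."""


class ConfigurationError(SaxsredError, ValueError):
    """Instrument or run configuration is invalid or incomplete."""


class RangeError(SaxsredError, ValueError):
    """Requested data range is empty or does not overlap the input."""
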