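"""Exception hierarchy for isletpulse.

Every error raised by the library derives from :class:`IsletPulseError`
so callers can catch the whole family with one clause.
"""


class IsletPulseError(Exception):
    """Base class for all isletpulse errors."""


class ConfigError(IsletPulseError):
    """Required configuration (e.g. the sampling rate) is missing or invalid."""


class ParseError(IsletPulseError):
    """A file could not be parsed into the expected tabular structure."""


class ValidationError(IsletPulseError):
    """A domain object violates one of its invariants."""


class GeometryError(IsletPulseError):
    """An ROI or coordinate set is inconsistent with the image or islet."""


class DegenerateTraceError(IsletPulseError):
    """A trace cannot be normalized (constant, or non-positive baseline)."""


class ProtocolError(IsletPulseError):
    """A stimulus protocol is inconsistent with the recording."""


class NoResponseError(IsletPulseError):
    """No cell responded to any stimulus, so no first responder exists."""


class DegenerateFitError(IsletPulseError):
    """A regression cannot be fitted (too few points or constant predictor)."""
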