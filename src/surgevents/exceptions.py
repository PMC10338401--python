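"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`SurgeventsError`, so
callers (and the CLI) can distinguish expected failure modes from bugs.
"""


class SurgeventsError(Exception):
    """Base class for all errors raised by surgevents."""


class ProfileError(SurgeventsError):
    """A system profile could not be loaded (missing template, bad reference)."""


class ValidationError(SurgeventsError):
    """A domain object violates one of its invariants."""


class GeometryError(SurgeventsError):
    """Pixel geometry mismatch: ROI outside frame, odd stereo width, ..."""


class ScanError(SurgeventsError):
    """A video frame could not be read or scanned."""


class ParameterError(SurgeventsError):
    """A numeric parameter is out of its admissible range."""


class ParseError(SurgeventsError):
    """An annotation file could not be parsed."""


class PairingError(SurgeventsError):
    """START/STOP label events could not be paired into intervals."""


class PackingError(SurgeventsError):
    """Requested synthetic intervals do not fit into the available duration."""


class VideoIOError(SurgeventsError):
    """A video file could not be read or written."""
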