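"""Exception hierarchy shared across the package.

``ValidationError`` signals a semantically invalid request or object
(bad coordinates, inconsistent parameters); ``FormatError`` signals
syntactically broken input files.  Plain ``OSError`` is used for I/O
failures so callers can distinguish the three classes of failure.
"""


class FusionscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FusionscreenError):
    """A value or combination of values violates a documented contract."""


class FormatError(FusionscreenError):
    """An input file does not conform to its declared format."""
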