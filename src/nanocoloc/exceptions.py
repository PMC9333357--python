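"""Exception types shared across the package."""


class NanocolocError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NanocolocError):
    """A file does not conform to the expected table/image format."""


class ParseError(FormatError):
    """A cell in a localization table could not be parsed as a number."""


class ConfigurationError(NanocolocError):
    """A threshold or parameter set is incomplete or inconsistent."""


class DegenerateInputError(NanocolocError):
    """An operation received input on which it is mathematically undefined
    (e.g. a nearest-neighbor distance of a single point)."""


class TraceError(NanocolocError):
    """A FRAP trace cannot be corrected or normalized (e.g. reference
    intensity at or below background, or zero bleach depth)."""
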