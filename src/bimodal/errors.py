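"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`BimodalError`,
so callers can catch one type at an application boundary (the CLI does).
"""


class BimodalError(Exception):
    """Base class for all package errors."""


class ParseError(BimodalError):
    """A file could not be parsed (ragged rows, bad header, empty input)."""


class ValidationError(BimodalError):
    """Inputs are structurally valid but inconsistent with each other."""


class DegenerateGeneError(BimodalError):
    """All signals identical: no two-way partition with u > l exists."""


class InsufficientDataError(BimodalError):
    """Too few usable signals to partition a gene."""


class DegenerateAnchorError(BimodalError):
    """Normalization anchors collapse (T == l or T == u)."""


class UndefinedDistanceError(BimodalError):
    """Cosine distance requested against a zero-norm profile."""
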