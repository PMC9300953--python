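"""Exception hierarchy shared across the package."""


class SighubError(Exception):
    """Base class for all package errors."""


class ParameterError(SighubError, ValueError):
    """A parameter is outside its documented range."""


class DegenerateInputError(SighubError, ValueError):
    """Input is structurally valid but statistically degenerate
    (constant vector, no events, identical groups where variance is needed)."""


class FormatError(SighubError, ValueError):
    """A file violates its declared tabular format; message names the line."""


class CoverageError(SighubError, ValueError):
    """Too few of the required genes/markers are present in the matrix."""
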