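"""Exception hierarchy shared across the package."""


class EdematrackError(Exception):
    """Base class for all package errors."""


class FormatError(EdematrackError):
    """A file on disk does not conform to its declared format."""


class ValidationError(EdematrackError):
    """Data violates a documented invariant (non-binary mask, bad fractions...)."""


class GeometryError(EdematrackError):
    """Two volumes that must share a grid/affine do not."""


class ParameterError(EdematrackError):
    """A caller-supplied parameter is out of its valid domain."""


class SchemeError(EdematrackError):
    """The gradient scheme cannot support the requested fit."""


class UndefinedMetricError(EdematrackError):
    """A ratio metric has a zero denominator (e.g. PIV with empty CST)."""
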