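"""Exception hierarchy shared across the package."""


class ColonnadeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ColonnadeError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive spacing)."""


class InvalidSpecError(ColonnadeError, ValueError):
    """A synthetic type specification is inconsistent (e.g. unknown partner)."""


class InsufficientDataError(ColonnadeError, ValueError):
    """Too few (or too degenerate) data points for the requested operation."""


class DegenerateColumnError(ColonnadeError, ValueError):
    """A synapse cloud collapsed entirely during outlier trimming."""


class NoIntersectionError(ColonnadeError, ValueError):
    """A column axis runs parallel to a bounding surface."""


class InfeasiblePinError(ColonnadeError, ValueError):
    """No ordered sublist satisfies the maximum-gap constraint."""


class MarkerResolutionError(ColonnadeError, ValueError):
    """A layer-boundary marker spec names a peak that does not exist."""


class InvalidDepthError(ColonnadeError, ValueError):
    """A depth value lies outside the unit interval."""


class SchemaError(ColonnadeError, ValueError):
    """A tabular input violates its documented column schema."""


class SWCFormatError(ColonnadeError, ValueError):
    """An SWC skeleton file is malformed (bad columns, cycles, empty)."""
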