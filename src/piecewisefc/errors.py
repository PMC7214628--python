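"""Exception types shared across the package."""


class PiecewiseFCError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PiecewiseFCError, ValueError):
    """An argument is outside its admissible range or inconsistent."""


class ValidationError(PiecewiseFCError, ValueError):
    """A data container violates one of its invariants."""


class FormatError(PiecewiseFCError, ValueError):
    """A file could not be parsed under the named format."""


class StratificationError(PiecewiseFCError, ValueError):
    """A cross-validation fold would lack one of the two conditions."""
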