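"""Exception hierarchy.

All errors raised on bad input derive from :class:`NucleofootError` and from
``ValueError`` so callers can catch either.
"""


class NucleofootError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NucleofootError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(NucleofootError, ValueError):
    """An in-memory object or argument violates a documented invariant."""


class ParameterError(NucleofootError, ValueError):
    """An operation was called with parameters outside its domain."""


class ConfigurationError(NucleofootError, ValueError):
    """A simulator or pipeline configuration is internally inconsistent."""


class DegenerateNullError(NucleofootError, ValueError):
    """A permutation null distribution has zero spread; no z-score exists."""


class FitError(NucleofootError, RuntimeError):
    """A model fit failed on degenerate input."""
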