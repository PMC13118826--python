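"""Exception hierarchy shared across the pipeline.

Validation errors mean the *input* is unusable (bad value, missing field,
mismatched grids); computation errors mean a well-formed input defeated the
numerics (too few usable points, degenerate parameters).
"""


class GlasstabError(Exception):
    """Base class for all package errors."""


class ValidationError(GlasstabError, ValueError):
    """Input fails a precondition or invariant."""


class DomainError(ValidationError):
    """Numeric argument outside its physical domain (negative density, ...)."""


class AlignmentError(ValidationError):
    """Two profiles do not share the grid a comparison requires."""


class NotFoundError(GlasstabError, KeyError):
    """Lookup of an unknown material or group name."""


class FitError(GlasstabError, RuntimeError):
    """A model fit or summary has too little usable data."""
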