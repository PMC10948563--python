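"""Exception hierarchy shared across the pipeline stages."""


class RootplastError(Exception):
    """Base class for all package errors."""


class ValidationError(RootplastError):
    """Raised when inputs violate a schema or parameter invariant."""


class GapError(ValidationError):
    """Raised when a plot is missing one or more depth strata."""


class UndefinedIndexError(RootplastError):
    """Raised when a plasticity index is undefined for the given inputs
    (e.g. zero mean, both treatment means zero)."""
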