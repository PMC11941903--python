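"""Exception types shared across the package."""


class EdgestageError(Exception):
    """Base class for all package errors."""


class ParseError(EdgestageError):
    """A file could not be parsed (malformed row, bad header, ...)."""


class ValidationError(EdgestageError):
    """Inputs violate a documented precondition or invariant."""


class DesignError(ValidationError):
    """A synthetic cohort design is internally infeasible."""
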