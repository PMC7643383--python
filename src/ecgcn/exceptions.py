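"""Exception hierarchy for input validation and file parsing."""


class EcgcnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EcgcnError):
    """A tabular input is missing required columns or has a malformed header."""


class ValidationError(EcgcnError):
    """An input value violates a documented precondition or invariant."""


class FormatError(EcgcnError):
    """A data file could not be parsed (ragged rows, non-numeric cells, ...)."""
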