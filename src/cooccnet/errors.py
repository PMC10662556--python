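"""Exception hierarchy for cooccnet.

All package errors derive from :class:`CooccnetError` so callers (and the
CLI) can catch one base class and map it to a nonzero exit status.
"""


class CooccnetError(Exception):
    """Base class for all cooccnet errors."""


class ConfigurationError(CooccnetError):
    """A required column, option, or mapping is missing or malformed."""


class EmptyInputError(CooccnetError):
    """The input contained no usable data rows."""


class DataRowError(CooccnetError):
    """A single data row is invalid (blank gene or attribute value).

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnknownGeneError(CooccnetError, KeyError):
    """A gene identifier is not present in the table or matrix."""

    def __init__(self, gene: str):
        super().__init__(f"unknown gene: {gene!r}")
        self.gene = gene


class UnknownAttributeError(CooccnetError, KeyError):
    """An attribute name is not configured for the table."""

    def __init__(self, attribute: str):
        super().__init__(f"unknown attribute: {attribute!r}")
        self.attribute = attribute


class VocabularyTooLargeError(CooccnetError):
    """Brute-force subset enumeration refused: 2^K would blow up.

    The closed-form fast path (``attribute_distance``) handles any
    vocabulary size.
    """


class SpecValidationError(CooccnetError):
    """A synthetic-data spec is internally inconsistent."""
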