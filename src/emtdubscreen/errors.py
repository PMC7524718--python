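"""Exception types shared across the pipeline stages."""


class EmtScreenError(ValueError):
    """Base class for all pipeline errors."""


class ParseError(EmtScreenError):
    """Malformed input file (bad header, non-numeric cell, empty file)."""


class DomainError(EmtScreenError):
    """Value outside the mathematical domain of an operation."""


class MissingGeneError(EmtScreenError):
    """A required gene symbol is absent from an expression matrix."""


class InsufficientDataError(EmtScreenError):
    """Fewer pairwise-complete observations than the operation requires."""


class UndefinedCorrelationError(EmtScreenError):
    """Correlation requested on a zero-variance vector."""


class CutpointError(EmtScreenError):
    """No valid cut-point exists in the scanned quantile window."""


class UndefinedTestError(EmtScreenError):
    """A statistical test is undefined for the given data (e.g. no events)."""
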