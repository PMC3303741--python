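"""Exception hierarchy for trinet."""


class TrinetError(Exception):
    """Base class for all trinet errors."""


class ValidationError(TrinetError, ValueError):
    """Input data violates a container invariant (duplicate ids, NaNs, ...)."""


class FormatError(TrinetError, ValueError):
    """Unknown or malformed file format."""


class UnknownGeneError(TrinetError, KeyError):
    """A gene identifier was not found in the expression matrix."""


class CyclicNetworkError(TrinetError, ValueError):
    """A directed cycle appeared where a DAG is required."""


class ScoreNumericalError(TrinetError, ArithmeticError):
    """The posterior matrix for a score term is singular or indefinite."""


class NotRankableError(TrinetError, LookupError):
    """A network cannot be located in an exhaustive DAG ranking
    (typically because it contains a directed cycle)."""
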