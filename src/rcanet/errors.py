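"""Exception hierarchy.

``RcanetError`` is the base for everything this package raises on bad
input or failed computation.  ``ValidationError`` subclasses map to CLI
exit code 2, everything else to exit code 1.
"""


class RcanetError(Exception):
    """Base class for all rcanet errors."""


class ValidationError(RcanetError):
    """Invalid user input: bad parameter values, inconsistent inputs."""


class FormatError(ValidationError):
    """A file does not follow the expected text layout."""


class ParseError(FormatError):
    """A cell/field could not be parsed; carries row/column coordinates."""


class IdentifierCollisionError(ValidationError):
    """Duplicate gene or sample identifier where uniqueness is required."""


class AlignmentError(ValidationError):
    """Gene/sample identifier orders of two matrices do not match."""


class ShapeError(ValidationError):
    """Matrix dimensions are not conformable."""


class UndefinedMeasureError(RcanetError):
    """Sparseness requested for an all-zero vector."""


class ConvergenceError(RcanetError):
    """Iterative procedure failed to converge.

    Attributes
    ----------
    iterations : int
        Number of iterations performed before giving up.
    """

    def __init__(self, message: str, iterations: int = -1):
        super().__init__(message)
        self.iterations = iterations
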