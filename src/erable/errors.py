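"""Exception hierarchy shared across the package."""


class ErableError(Exception):
    """Base class for all errors raised by this package."""


class TreeError(ErableError, ValueError):
    """Invalid tree structure or an operation unsupported on this tree."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class InputFormatError(ErableError, ValueError):
    """Malformed input file (multi-matrix, alignment, truth tables...)."""


class NoComparableSites(ErableError):
    """A sequence pair shares no site where both have a determinate base."""


class GeneRejectedError(ErableError, ValueError):
    """A gene matrix carries too little signal to enter the solver."""


class DegenerateSystemError(ErableError, ArithmeticError):
    """The constrained least-squares system admits no solution at the
    requested constraint value (e.g. every gene matrix is all zero)."""
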