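"""Exception hierarchy.

``DelimkitError`` is the common base; ``InputError`` covers malformed user
inputs (exit code 1 in the CLI), everything else is a runtime failure (exit
code 2).
"""


class DelimkitError(Exception):
    """Base class for all delimkit errors."""


class InputError(DelimkitError):
    """Malformed or inconsistent user input (files, config, tables)."""


class AlignmentError(InputError):
    """Alignment invariant violated (ragged lengths, bad characters, ...)."""


class UndefinedDistanceError(DelimkitError):
    """A pairwise distance is undefined (zero comparable sites)."""


class UltrametricityError(InputError):
    """Tree is not ultrametric within tolerance."""


class ClassificationError(DelimkitError):
    """A delimited unit matched no classification rule."""


class OptimizationError(DelimkitError):
    """Numerical optimization failed to converge."""
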