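"""Exception types shared across the package."""


class P300LabError(Exception):
    """Base class for package errors."""


class ParameterError(P300LabError, ValueError):
    """An argument value is outside its documented domain."""


class DimensionError(P300LabError, ValueError):
    """Array shapes are inconsistent with the operation's contract."""


class FormatError(P300LabError, ValueError):
    """A serialized container is malformed; message names the offending field."""


class BoundsError(P300LabError, IndexError):
    """An epoch window falls outside the continuous record."""


class ClassError(P300LabError, ValueError):
    """Label vector does not contain the classes the operation requires."""


class StratificationError(P300LabError, ValueError):
    """A class has fewer members than the requested number of folds."""


class ConvergenceError(P300LabError, RuntimeError):
    """An iterative solver did not reach its tolerance within max_iter."""


class SPDError(P300LabError, ValueError):
    """A matrix expected to be symmetric positive-definite is not."""
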