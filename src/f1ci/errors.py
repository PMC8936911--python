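"""Exception hierarchy for f1ci.

All errors carry human-readable messages naming the offending file, cell,
or class so that CLI users can locate the problem without a traceback.
"""


class F1CIError(Exception):
    """Base class for all f1ci errors."""


class InputError(F1CIError):
    """Invalid user input (mismatched label sequences, bad alpha, n = 0...)."""


class FormatError(F1CIError):
    """A file could not be parsed as a confusion matrix or probability table."""


class DegenerateClassError(F1CIError):
    """A class is absent from both the predicted and true margins.

    The per-class F1 is then 0/0 and the macro-averaged F1 is undefined
    unless the empty class is explicitly dropped.
    """

    def __init__(self, message: str, classes=()):
        super().__init__(message)
        self.classes = tuple(classes)


class UndefinedEstimatorError(F1CIError):
    """maF1* (or its variance) is undefined because a margin is zero."""

    def __init__(self, message: str, classes=()):
        super().__init__(message)
        self.classes = tuple(classes)


class OracleError(F1CIError):
    """The finite-difference delta-method engine hit an undefined score."""
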