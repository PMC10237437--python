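"""Exception hierarchy shared by all kleevec modules."""


class KleeVecError(Exception):
    """Base class for all kleevec errors."""


class InputError(KleeVecError):
    """Invalid user-provided input (bad grouping table, duplicate ids, ...)."""


class AlignmentError(InputError):
    """The input is not a valid multiple sequence alignment."""


class FormatError(KleeVecError):
    """A kleevec on-disk artifact is corrupt or has the wrong format."""


class MergeError(KleeVecError):
    """Two artifacts cannot be merged (e.g. shared set names)."""


class ConsistencyError(KleeVecError):
    """Artifacts that must describe the same data do not agree."""


class DegenerateContrastError(KleeVecError):
    """A contrast matrix has no positive eigenvalue; no indicator vector exists."""

    def __init__(self, message: str, eigenvalue: float | None = None):
        super().__init__(message)
        self.eigenvalue = eigenvalue


class ConvergenceError(KleeVecError):
    """The iterative eigensolver failed to converge."""
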