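"""Exception hierarchy for pmnmix.

All pmnmix errors derive from :class:`PmnmixError` so callers can catch the
package's failures with a single except clause while still distinguishing
shape problems (bad input) from numerical failures (bad data / bad luck).
"""


class PmnmixError(Exception):
    """Base class for all pmnmix errors."""


class ShapeError(PmnmixError, ValueError):
    """Arrays are not conformable or have unexpected dimensions."""


class DefinitenessError(PmnmixError, ValueError):
    """A matrix required to be symmetric positive definite is not.

    Carries ``matrix_name`` so callers know which factor (row or column
    covariance, or a scenario precision) failed.
    """

    def __init__(self, message, matrix_name=None):
        super().__init__(message)
        self.matrix_name = matrix_name


class RankDeficiencyError(PmnmixError, ValueError):
    """A scatter matrix is singular; more samples (or a ridge) are needed."""


class SingularityError(PmnmixError, ValueError):
    """An unpenalized precision solve was requested on a singular scatter."""


class ConvergenceError(PmnmixError, RuntimeError):
    """An iterative solver exhausted its iteration budget.

    ``last`` holds the final iterates so callers can inspect or resume.
    """

    def __init__(self, message, last=None):
        super().__init__(message)
        self.last = last


class EmptyClusterError(PmnmixError, RuntimeError):
    """A mixture component's total responsibility fell below the floor."""


class DegenerateSampleError(PmnmixError, RuntimeError):
    """Every component density underflowed for some observation."""

    def __init__(self, message, row=None):
        super().__init__(message)
        self.row = row


class FitFailureError(PmnmixError, RuntimeError):
    """All EM restarts failed; the message summarizes per-restart causes."""


class ModelFormatError(PmnmixError, ValueError):
    """A serialized model document is malformed or has the wrong version."""
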