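"""Exception taxonomy shared across the package.

The CLI maps these onto process exit codes: usage errors (including
capability errors for unsupported method/estimand combinations) exit 2,
validation errors (including rank/degeneracy problems) exit 3, and
solver non-convergence exits 4.
"""


class IPDError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(IPDError):
    """The call itself is malformed: bad argument values or combinations."""

    exit_code = 2


class CapabilityError(UsageError):
    """A well-formed request for something the method does not support."""

    exit_code = 2


class ValidationError(IPDError):
    """The supplied data violates a documented contract."""

    exit_code = 3

    exit_code = 3


class FormulaError(UsageError):
    """The model formula string could not be parsed."""


class RankError(ValidationError):
    """A design or Jacobian matrix is singular or rank deficient."""


class DegeneratePredictorError(ValidationError):
    """The prediction column carries no information (zero variance)."""


class ConvergenceError(IPDError):
    """An iterative solver failed to converge; carries its iteration trace."""

    exit_code = 4

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []
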