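"""Exception hierarchy for groupmediate."""


class GroupMediateError(Exception):
    """Base class for all package-specific errors."""


class DataError(GroupMediateError):
    """Invalid or unusable input data (missing columns, bad labels, NaNs...)."""


class ConfigError(GroupMediateError):
    """Invalid analysis configuration (e.g. method/approach mismatch)."""


class EstimationError(GroupMediateError):
    """Model estimation failed."""


class CollinearityError(EstimationError):
    """Rank-deficient design matrix.

    Carries the name of the offending column in ``column``.
    """

    def __init__(self, column: str, message: str | None = None):
        self.column = column
        super().__init__(message or f"design matrix is collinear in column {column!r}")


class ConvergenceError(EstimationError):
    """Iterative estimation did not converge.

    ``last_params`` holds the final iterate and ``grad_norm`` the max-norm of
    the gradient at that iterate (when available).
    """

    def __init__(self, message, last_params=None, grad_norm=None):
        self.last_params = last_params
        self.grad_norm = grad_norm
        super().__init__(message)


class SimulationError(GroupMediateError):
    """A simulation condition failed (e.g. too many failed replications)."""
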