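"""Exception hierarchy shared across the package."""


class RSCCAError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RSCCAError, ValueError):
    """Raised when inputs violate a documented precondition."""


class DegenerateInputError(RSCCAError, ValueError):
    """Raised when inputs are formally valid but numerically degenerate
    (zero variance, singular scatter, rank-deficient design, ...)."""


class RankDeficiencyError(RSCCAError, ValueError):
    """Raised when an unpenalized least-squares step is requested on a
    design with at least as many predictors as observations."""


class SelectionError(RSCCAError, RuntimeError):
    """Raised when model selection cannot produce a usable fit."""
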