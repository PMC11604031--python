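"""Exception hierarchy shared across the package."""


class KLDomainError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(KLDomainError, ValueError):
    """A scalar or structural argument is outside its admissible range."""


class InvalidInputError(KLDomainError, ValueError):
    """Input data (curves, index sets, files) violate a precondition."""


class InsufficientSampleError(KLDomainError, ValueError):
    """Too few curves to carry out the requested estimation."""


class NotPositiveDefiniteError(KLDomainError, ValueError):
    """A covariance factorization failed; carries the offending matrix name."""

    def __init__(self, name: str, detail: str = ""):
        self.matrix_name = name
        msg = f"matrix {name!r} is not positive definite"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class EstimationFailureError(KLDomainError, RuntimeError):
    """An estimation procedure (e.g. cross-validation) found no usable fit."""
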