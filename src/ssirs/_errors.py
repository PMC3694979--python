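"""Exception hierarchy shared across the package."""


class SsirsError(Exception):
    """Base class for all package errors."""


class ValidationError(SsirsError, ValueError):
    """Invalid input data or configuration; ``field`` names the offender."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class ConvergenceError(SsirsError, RuntimeError):
    """Maximum-likelihood fit failed to converge (e.g. perfect separation)."""


class CollinearityError(SsirsError, ValueError):
    """Rank-deficient design matrix; ``columns`` lists the collinear labels."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class DegenerateOutcomeError(SsirsError, ValueError):
    """Outcome vector is constant: no maximum-likelihood estimate exists."""
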