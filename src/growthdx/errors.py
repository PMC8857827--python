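"""Exception hierarchy shared across the package."""


class GrowthDxError(Exception):
    """Base class for all package errors."""


class MissingFieldError(GrowthDxError):
    """A required record field is absent; nothing is imputed silently."""


class GARangeError(GrowthDxError, ValueError):
    """Gestational age outside the supported range."""


class DomainError(GrowthDxError, ValueError):
    """A numeric argument violates a mathematical precondition."""


class OutOfCoverageError(GrowthDxError):
    """A lookup fell outside a reference table's grid; never extrapolated."""


class CohortValidationError(GrowthDxError):
    """One or more cohort rows failed strict parsing."""

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.row_errors[:10])
        extra = "" if len(self.row_errors) <= 10 else f" (+{len(self.row_errors) - 10} more)"
        super().__init__(f"{len(self.row_errors)} invalid cohort row(s): {lines}{extra}")


class EmptyAnalysisError(GrowthDxError):
    """No eligible records remain after exclusions."""
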