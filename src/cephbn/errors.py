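"""Exception hierarchy shared across the package."""


class CephbnError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CephbnError):
    """A file or table does not have the expected layout (e.g. missing column)."""


class CohortValidationError(CephbnError):
    """One or more patient rows violate the cohort invariants.

    Carries ``diagnostics``: a list of (patient_id, message) pairs.
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(f"{pid}: {msg}" for pid, msg in self.diagnostics)
        super().__init__(f"invalid patient rows: {lines}")


class CoverageError(CephbnError):
    """A reference table does not cover a requested (feature, age) point."""


class UndefinedCorrelationError(CephbnError):
    """Pearson correlation requested for a constant sequence."""


class ConstraintError(CephbnError):
    """Whitelist/blacklist sets are inconsistent or unsatisfiable."""


class ScoringError(CephbnError):
    """A local BIC score could not be computed (e.g. singular design)."""


class FittingError(CephbnError):
    """Least-squares parameter estimation failed for a node."""


class QueryError(CephbnError):
    """A conditional-probability query is malformed."""
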