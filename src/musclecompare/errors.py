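"""Exception types shared across the package."""


class MuscleCompareError(Exception):
    """Base class for package errors."""


class DomainError(MuscleCompareError, ValueError):
    """An input lies outside the mathematical domain of an equation."""


class UnclassifiableError(MuscleCompareError):
    """Covariates fall outside every stratum of a cut-off set or normative table."""


class SingularFitError(MuscleCompareError):
    """The regression design matrix is rank deficient."""


class CohortValidationError(MuscleCompareError):
    """One or more rows of a cohort file failed schema validation.

    Attributes
    ----------
    row_errors : list of (row_number, message)
        1-based data-row numbers (header excluded) with a description of the
        failure, including a unit hint where the magnitude suggests one.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = [f"row {row}: {msg}" for row, msg in self.row_errors]
        super().__init__("cohort validation failed:\n" + "\n".join(lines))
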