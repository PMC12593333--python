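"""Exception hierarchy.

Every error raised by the estimators carries the name of the failing stage so
that pipeline drivers (CLI, simulation engine) can report a machine-readable
category.
"""


class R2slsError(Exception):
    """Base class for all package errors."""

    category = "error"


class DegenerateInputError(R2slsError):
    """Input violates a precondition (constant column, zero variance, ...)."""

    category = "degenerate-input"


class SingularDesignError(R2slsError):
    """A required Gram matrix is singular or numerically near-singular."""

    category = "singular-design"


class CorrectionNotApplicable(R2slsError):
    """Stage-1 R-squared too small for the attenuation correction.

    Callers are expected to fall back to the uncorrected null test.
    """

    category = "correction-not-applicable"


class ConvergenceError(R2slsError):
    """Iterative invalid-IV search failed to converge; carries the score path."""

    category = "non-convergence"

    def __init__(self, message, path=None):
        super().__init__(message)
        self.path = path


class HarmonizationError(R2slsError):
    """Summary datasets could not be aligned on a shared, allele-consistent SNP set."""

    category = "harmonization"
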