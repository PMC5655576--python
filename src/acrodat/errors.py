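"""Exception hierarchy.

Validation failures (bad measurements, malformed files, infeasible designs)
map to CLI exit code 2; numerical non-convergence maps to exit code 3.
"""


class AcrodatError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(AcrodatError):
    """Invalid input data, configuration, or request."""

    exit_code = 2


class InvalidMeasurementError(ValidationError):
    """A clinical measurement violates its invariants (e.g. LLN >= ULN)."""


class InvalidResponseError(ValidationError):
    """A questionnaire response has the wrong item count or out-of-range items."""


class IncompleteRecordError(ValidationError):
    """A patient record is missing one of the five required components."""


class InvalidScenarioError(ValidationError):
    """A scenario id outside [1, 243] or a malformed level vector."""


class InfeasibleDesignError(ValidationError):
    """A survey design that cannot be satisfied (e.g. per_rater > 243)."""


class ParseError(ValidationError):
    """A ratings or patients file that cannot be parsed; names the offending row."""


class UnbalancedTableError(ValidationError):
    """Listed scenarios were not all rated by the same number of raters."""


class UndefinedAgreementError(ValidationError):
    """Pairwise agreement requested with fewer than 2 raters."""


class DegenerateKappaError(ValidationError):
    """Fleiss' kappa undefined: all assessments fell in a single category."""


class InsufficientDataError(ValidationError):
    """An analysis needs long-format per-rater ratings, not just counts."""


class GateViolationError(ValidationError):
    """Probability combination requested for a gate-triggering level vector."""


class NotFittedError(AcrodatError):
    """Prediction requested from an unfitted model."""

    exit_code = 2


class ConvergenceError(AcrodatError):
    """A logistic submodel failed to converge (likely complete separation)."""

    exit_code = 3


class DegenerateModelError(AcrodatError):
    """A submodel cannot be fit (e.g. no non-stable rows for the second stage)."""

    exit_code = 3


class CoherenceWarning(UserWarning):
    """Literal probability combination produced a negative mild-activity mass."""
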