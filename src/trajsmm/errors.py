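"""Exception types shared across trajsmm modules."""


class TrajsmmError(Exception):
    """Base class for all package errors."""


class DataValidationError(TrajsmmError, ValueError):
    """Malformed or inconsistent input data (schema, duplicates, ranges)."""


class DomainError(TrajsmmError, ValueError):
    """A value outside the mathematical domain of an operation."""


class ExtrapolationError(DomainError):
    """Evaluation requested outside the fitted month range."""


class RankDeficientError(TrajsmmError, ValueError):
    """Unpenalized spline system is singular (design not full column rank)."""


class DegenerateClassError(TrajsmmError, RuntimeError):
    """A latent class became empty during the E-M iterations."""

    def __init__(self, class_index: int, iteration: int | None = None):
        self.class_index = class_index
        self.iteration = iteration
        where = f" at iteration {iteration}" if iteration is not None else ""
        super().__init__(f"class {class_index} has no members{where}")


class SeparationError(TrajsmmError, RuntimeError):
    """Complete or quasi-complete separation in a logistic regression."""

    def __init__(self, predictor: str):
        self.predictor = predictor
        super().__init__(
            f"logistic fit diverged: separation involving predictor {predictor!r}"
        )


class ConvergenceError(TrajsmmError, RuntimeError):
    """An iterative fit exhausted its iteration budget."""


class PipelineError(TrajsmmError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
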