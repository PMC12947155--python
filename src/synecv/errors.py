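"""Exception hierarchy shared across the package."""


class SynEcvError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SynEcvError, ValueError):
    """A configuration or input table violates an invariant; the message names the field."""


class DomainError(SynEcvError, ValueError):
    """A numeric argument is outside the domain of an operation (non-finite, out of range, zero divisor)."""


class DegenerateDesignError(SynEcvError, ValueError):
    """A regression design matrix is rank deficient (constant regressor, single-level factor)."""


class InsufficientDataError(SynEcvError, ValueError):
    """Too few observations for the requested fit or interval."""


class EmptyMaskError(SynEcvError, ValueError):
    """A binary mask is (or became, after erosion) empty."""


class EmptyEvaluationError(SynEcvError, ValueError):
    """No record of a cohort could be scored under the given model."""
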