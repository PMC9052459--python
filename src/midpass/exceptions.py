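"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a structural or range constraint."""


class EstimationError(RuntimeError):
    """Raised when an estimator is undefined on the data it was given
    (single-class labels, empty anchor group, non-convergent fit, ...)."""


class DegenerateIntervalWarning(UserWarning):
    """A confidence interval collapsed to a point (zero variance or n = 1)."""


class LowSampleWarning(UserWarning):
    """An analysis subset is smaller than the configured floor."""
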