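"""Package-specific exceptions and warnings."""


class NoEventsError(ValueError):
    """Raised when a partial-likelihood computation receives zero events."""


class SingularInformationError(ValueError):
    """Raised when the observed information matrix is (numerically) singular,
    e.g. because of exactly collinear design columns."""


class MissingMediatorError(ValueError):
    """Raised at ingest when the mediator matrix contains missing values.

    Imputation is out of scope; callers must resolve missingness upstream.
    """


class DegenerateExposureError(ValueError):
    """Raised when the exposure is constant in the sample, so no
    exposure->mediator association is estimable."""


class ConvergenceWarning(UserWarning):
    """Emitted when an iterative fit stops without meeting its tolerance
    (e.g. monotone likelihood / separation in a Cox fit)."""
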