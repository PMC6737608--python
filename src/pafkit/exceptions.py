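"""Exception and warning taxonomy for pafkit."""


class PafkitError(Exception):
    """Base class for all pafkit errors."""


class InvalidArgumentError(PafkitError, ValueError):
    """An argument is non-finite or outside its mathematical domain."""


class DegenerateExposureError(PafkitError):
    """All controls sit at the reference level, so the control-weighted
    average log-odds ratio is undefined."""


class DegenerateLevelError(PafkitError):
    """An exposure level is absent among cases or among controls, so its
    odds ratio is not estimable."""


class FitFailureError(PafkitError):
    """Logistic model fitting failed (separation, singularity or
    non-convergence). ``diagnostics`` carries whatever the optimizer left."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class BootstrapFailureError(PafkitError):
    """Too many (or all) bootstrap resamples failed to refit."""


class PafkitWarning(UserWarning):
    """Base class for pafkit warnings."""


class NegativeEffectWarning(PafkitWarning):
    """The averaged log-odds ratio is negative: the declared reference level
    is not the minimum-risk level. Results are returned unchanged; plots
    refuse negative values."""


class ApproximationRangeWarning(PafkitWarning):
    """The linear approximation left the [0, 1] range a proportion should
    occupy (it may exceed 1 for large odds ratios)."""
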