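"""Exception hierarchy for robustewas.

All errors raised by the library derive from :class:`RobustEwasError` so
callers (notably the CLI) can distinguish our domain errors from bugs.
"""


class RobustEwasError(Exception):
    """Base class for all robustewas errors."""


class DegeneratePredictorError(RobustEwasError):
    """The tested variable has zero variance; its coefficient is undefined."""


class InsufficientSampleError(RobustEwasError):
    """Too few complete samples to fit the requested model."""


class CollinearityError(RobustEwasError):
    """The design matrix is rank deficient (collinear covariates)."""


class InvalidFoldCountError(RobustEwasError):
    """Requested fold count k is outside 1..n."""


class InsufficientFoldSizeError(RobustEwasError):
    """A fold would be smaller than the minimum needed for a valid fit."""


class EmptyMetaError(RobustEwasError):
    """Meta-analysis requires at least one fold statistic."""
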