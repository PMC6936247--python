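"""Exception hierarchy for isoniche.

Validation problems (bad tables, bad settings) raise subclasses of
:class:`ValidationError`; numerical problems (degenerate covariances,
failed decompositions) raise subclasses of :class:`NumericalError`.
The CLI maps these onto exit codes 2 and 3 respectively.
"""


class IsonicheError(Exception):
    """Base class for all isoniche errors."""


class ValidationError(IsonicheError, ValueError):
    """Invalid user input: malformed tables, out-of-range settings."""


class NumericalError(IsonicheError, ValueError):
    """Numerical failure: degenerate covariance, failed decomposition."""


class InsufficientSampleError(ValidationError):
    """Too few observations to estimate a trivariate covariance."""


class DegenerateCovarianceError(NumericalError):
    """Covariance (or shape) matrix is singular or not positive definite."""


class CoverageError(ValidationError):
    """Coverage fraction outside the open interval (0, 1)."""


class ScaleMismatchError(ValidationError):
    """Two ellipsoids compared at different coverage scales."""


class PairingError(ValidationError):
    """Posterior draw sets cannot be paired (unequal retained counts)."""
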