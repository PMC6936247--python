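"""Standard ellipsoids for trivariate-normal data.

The standard ellipsoid is the three-dimensional analogue of the standard
ellipse familiar from bivariate isotope analyses: the surface of squared
Mahalanobis radius 1 around the sample mean, whose semi-axes ``a >= b >= c``
are the square roots of the covariance eigenvalues.  Its volume

    SEV = (4/3) * pi * a * b * c = (4/3) * pi * sqrt(det(Sigma))

is the standard ellipsoid volume.  Under trivariate normality the 1-sigma
ellipsoid captures ``P(chi2_3 <= 1) ~= 19.9%`` of the population; rescaling
the shape matrix by the chi-square(3) quantile ``q_p`` yields an ellipsoid
capturing any desired proportion ``p``.

Sample covariances use the unbiased ``n - 1`` denominator.  The
small-sample correction ``SEV_C = SEV * (n - 1) / (n - 3)`` therefore must
not be applied twice; it is exposed separately as :func:`sev_c`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .exceptions import (
    CoverageError,
    DegenerateCovarianceError,
    InsufficientSampleError,
)

__all__ = [
    "SIGMA1_COVERAGE",
    "Ellipsoid",
    "ellipsoid_from_sample",
    "semi_axes",
    "sev",
    "sev_c",
    "scale_to_coverage",
    "mahalanobis_sq",
    "contains",
]

#: Mass of a trivariate normal inside its 1-sigma (standard) ellipsoid.
SIGMA1_COVERAGE: float = float(stats.chi2.cdf(1.0, df=3))

# Relative eigenvalue threshold below which a shape matrix is treated as
# singular rather than silently regularized.
_EIG_RTOL = 1e-12
_SYM_RTOL = 1e-8


def _validate_shape(shape: np.ndarray) -> np.ndarray:
    shape = np.asarray(shape, dtype=float)
    if shape.shape != (3, 3):
        raise DegenerateCovarianceError(
            f"shape matrix must be 3x3, got {shape.shape}"
        )
    scale = max(np.abs(shape).max(), 1.0)
    if not np.allclose(shape, shape.T, atol=_SYM_RTOL * scale):
        raise DegenerateCovarianceError("shape matrix is not symmetric")
    shape = 0.5 * (shape + shape.T)
    eigvals = np.linalg.eigvalsh(shape)
    if eigvals[-1] <= 0 or eigvals[0] <= _EIG_RTOL * eigvals[-1]:
        raise DegenerateCovarianceError(
            "degenerate covariance: eigenvalues "
            f"{eigvals} are not all positive"
        )
    return shape


@dataclasses.dataclass(frozen=True)
class Ellipsoid:
    """An ellipsoid in isotope space (delta13C, delta15N, delta34S; permil).

    Parameters
    ----------
    center : (3,) array_like
        Ellipsoid centre, permil on each axis.
    shape : (3, 3) array_like
        Symmetric positive-definite shape matrix (permil^2).  At the
        standard (1-sigma) state this is the covariance matrix itself; a
        rescaled ellipsoid stores the covariance multiplied by the
        chi-square(3) quantile of its coverage.
    coverage : float, optional
        Proportion of the generating trivariate normal the ellipsoid is
        scaled to capture.  Defaults to the 1-sigma value
        ``P(chi2_3 <= 1) ~= 0.1987`` so that a freshly fitted ellipsoid is
        the standard ellipsoid.
    n : int, optional
        Sample size used to build the ellipsoid (0 for synthetic or
        population ellipsoids).
    """

    center: np.ndarray
    shape: np.ndarray
    coverage: float = SIGMA1_COVERAGE
    n: int = 0

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        shape = _validate_shape(self.shape)
        if not 0.0 < self.coverage < 1.0:
            raise CoverageError(
                f"invalid coverage {self.coverage!r}: must lie in (0, 1)"
            )
        center.setflags(write=False)
        shape.setflags(write=False)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "n", int(self.n))

    # Convenience wrappers so model/results code reads naturally.
    @property
    def volume(self) -> float:
        return sev(self)

    def mahalanobis_sq(self, x: np.ndarray) -> np.ndarray:
        return mahalanobis_sq(self, x)

    def contains(self, x: np.ndarray, rtol: float = 0.0) -> np.ndarray:
        return contains(self, x, rtol=rtol)


def ellipsoid_from_sample(data: np.ndarray) -> Ellipsoid:
    """Fit the standard (1-sigma) ellipsoid to an ``n x 3`` isotope sample.

    The centre is the columnwise mean and the shape the unbiased
    (``n - 1`` denominator) sample covariance, decomposable into
    eigenvalues/eigenvectors for the semi-axes.

    Raises
    ------
    InsufficientSampleError
        If fewer than 4 rows are supplied.
    DegenerateCovarianceError
        If the sample covariance is singular (collinear data).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise InsufficientSampleError(
            f"expected an n x 3 matrix, got array of shape {data.shape}"
        )
    if np.isnan(data).any():
        raise InsufficientSampleError("input contains missing values")
    n = data.shape[0]
    if n < 4:
        raise InsufficientSampleError(
            f"insufficient sample: need at least 4 rows, got {n}"
        )
    center = data.mean(axis=0)
    cov = np.cov(data, rowvar=False, ddof=1)
    return Ellipsoid(center=center, shape=cov, n=n)


def semi_axes(e: Ellipsoid) -> np.ndarray:
    """Semi-axis lengths ``(a, b, c)`` with ``a >= b >= c > 0`` (permil).

    These are the square roots of the shape-matrix eigenvalues, sorted in
    descending order: one semimajor and two semiminor axes.
    """
    eigvals = np.linalg.eigvalsh(e.shape)
    return np.sqrt(eigvals[::-1])


def sev(e: Ellipsoid) -> float:
    """Ellipsoid volume ``(4/3) pi a b c`` (permil^3) at the stored scale.

    For the standard (1-sigma) ellipsoid this is the standard ellipsoid
    volume SEV, equal to ``(4/3) pi sqrt(det(shape))``.
    """
    sign, logdet = np.linalg.slogdet(e.shape)
    if sign <= 0:
        raise DegenerateCovarianceError("degenerate covariance: det <= 0")
    return float(4.0 / 3.0 * np.pi * np.exp(0.5 * logdet))


def sev_c(e: Ellipsoid, n: int | None = None) -> float:
    """Small-sample corrected volume ``SEV * (n - 1) / (n - 3)``.

    The degrees-of-freedom correction for a three-dimensional ellipsoid;
    always greater than SEV, converging to SEV as ``n`` grows.  ``n``
    defaults to the sample size stored on the ellipsoid.
    """
    if n is None:
        n = e.n
    n = int(n)
    if n <= 3:
        raise InsufficientSampleError(
            f"correction undefined for n = {n}: requires n >= 4"
        )
    return sev(e) * (n - 1) / (n - 3)


def scale_to_coverage(e: Ellipsoid, p: float) -> Ellipsoid:
    """Rescale an ellipsoid so it captures proportion ``p`` of the data.

    Under trivariate normality the squared Mahalanobis radius is
    chi-square with 3 degrees of freedom, so the ellipsoid capturing mass
    ``p`` is the Mahalanobis shell at radius^2 ``q_p = chi2_3^{-1}(p)``.
    The shape matrix is multiplied by ``q_p / q_current``; semi-axes scale
    by the square root of that ratio.
    """
    if not 0.0 < p < 1.0:
        raise CoverageError(f"invalid coverage {p!r}: must lie in (0, 1)")
    q_new = stats.chi2.ppf(p, df=3)
    q_old = stats.chi2.ppf(e.coverage, df=3)
    return Ellipsoid(
        center=e.center,
        shape=e.shape * (q_new / q_old),
        coverage=p,
        n=e.n,
    )


def mahalanobis_sq(e: Ellipsoid, x: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis radius of point(s) ``x`` w.r.t. the ellipsoid.

    Accepts a single 3-vector or an ``(..., 3)`` stack; returns a scalar
    or an array of matching leading shape.
    """
    x = np.asarray(x, dtype=float)
    diff = x - e.center
    try:
        L = np.linalg.cholesky(e.shape)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded in init
        raise DegenerateCovarianceError(str(err)) from err
    z = np.linalg.solve(L, diff[..., np.newaxis])[..., 0] if diff.ndim > 1 \
        else np.linalg.solve(L, diff)
    return np.sum(z * z, axis=-1)


def contains(e: Ellipsoid, x: np.ndarray, rtol: float = 0.0) -> np.ndarray:
    """True where ``x`` lies inside or on the ellipsoid at its stated scale.

    Membership is ``(x - c)^T shape^{-1} (x - c) <= 1 (+ rtol)``; the
    small optional tolerance admits points generated exactly on the
    surface.
    """
    return mahalanobis_sq(e, x) <= 1.0 + rtol
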