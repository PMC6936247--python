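"""Bayesian trivariate-normal niche estimation.

Each group's isotope data are modelled as draws from a trivariate normal
with unknown mean and covariance under a weakly informative conjugate
Normal-Inverse-Wishart prior:

    mu | Sigma ~ N(m0, Sigma / kappa0)
    Sigma      ~ Inverse-Wishart(nu0, Lambda0)

with defaults ``m0 = 0``, ``kappa0 = 1e-3``, ``Lambda0 = 1e-3 * I`` and
``nu0 = 0`` degrees of freedom — an objective, Jeffreys-style limit
(every positive ``nu0`` shrinks posterior volumes low: even ``nu0 = 4``,
the smallest value giving a finite prior mean, biases the
posterior-median volume by about -7% at n = 100, whereas ``nu0 = 0``
confines material underestimation to n <= 8).  Conjugacy gives exact
full conditionals, so the Gibbs sampler needs no tuning:

    mu | Sigma, X    ~ N((kappa0 m0 + n xbar) / kappa_n, Sigma / kappa_n)
    Sigma | mu, X    ~ IW(nu0 + n + 1,
                          Lambda0 + S_mu + kappa0 (mu - m0)(mu - m0)^T)

where ``kappa_n = kappa0 + n`` and ``S_mu`` is the scatter about ``mu``.

Posterior ellipsoid volumes (SEV_B, and EV_B when rescaled to 75%
coverage) are computed per covariance draw; pairwise overlap is computed
per *paired* draw so that posterior uncertainty in both groups propagates
into the overlap credible interval.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from . import mesh as mesh_mod
from .exceptions import (
    InsufficientSampleError,
    PairingError,
    ValidationError,
)
from .geometry import Ellipsoid, SIGMA1_COVERAGE, scale_to_coverage, sev

__all__ = [
    "NIWPrior",
    "PosteriorDraws",
    "VolumeSummary",
    "OverlapPosterior",
    "fit_posterior",
    "volume_posterior",
    "overlap_posterior",
    "classify_overlap",
    "small_sample_bias_sim",
    "DEFAULT_ITERATIONS",
    "DEFAULT_BURN_IN",
    "DEFAULT_THIN",
    "OVERLAP_ITERATIONS",
    "OVERLAP_BURN_IN",
    "OVERLAP_THIN",
]

# Default sampler settings for volume posteriors (EV_B) and for overlap
# posteriors.  The overlap run is shorter because every retained draw
# pair costs a full mesh intersection.
DEFAULT_ITERATIONS = 15_000
DEFAULT_BURN_IN = 10_000
DEFAULT_THIN = 25
OVERLAP_ITERATIONS = 7_500
OVERLAP_BURN_IN = 5_000
OVERLAP_THIN = 1

#: Overlap at or above this percentage is flagged as significant.
SIGNIFICANT_OVERLAP_PERCENT = 60.0


@dataclasses.dataclass(frozen=True)
class NIWPrior:
    """Normal-Inverse-Wishart hyperparameters.

    The defaults are vague: the prior mean carries negligible weight
    (``kappa0 = 1e-3``), the Inverse-Wishart scale is a small multiple of
    the identity, and ``df = 0`` takes the objective Jeffreys-style limit
    (the prior itself is then improper, but every Gibbs conditional and
    the joint posterior are proper for n >= 4).  Positive ``df`` adds
    pseudo-observations of the near-zero scale matrix and systematically
    shrinks posterior volumes; keep it at 0 unless genuine prior
    information about the covariance exists.
    """

    mean: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3)
    )
    kappa: float = 1e-3
    scale: np.ndarray = dataclasses.field(
        default_factory=lambda: 1e-3 * np.eye(3)
    )
    df: float = 0.0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(3)
        scale = np.asarray(self.scale, dtype=float).reshape(3, 3)
        if self.kappa <= 0:
            raise ValidationError("prior kappa must be positive")
        if self.df < 0:
            raise ValidationError("prior df must be non-negative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "scale", scale)


@dataclasses.dataclass(frozen=True)
class PosteriorDraws:
    """Paired posterior draws of the group mean and covariance.

    ``means[k]`` and ``covariances[k]`` come from the same retained Gibbs
    iteration; pairing by index is what lets downstream overlap code
    propagate joint uncertainty.
    """

    means: np.ndarray
    covariances: np.ndarray
    settings: dict

    def __post_init__(self) -> None:
        if self.means.shape[0] != self.covariances.shape[0]:
            raise PairingError(
                "means and covariances must have equal draw counts"
            )

    @property
    def n_draws(self) -> int:
        return self.means.shape[0]

    def ellipsoid(self, index: int, coverage: float | None = None) -> Ellipsoid:
        """Standard ellipsoid of draw ``index``, optionally rescaled."""
        e = Ellipsoid(
            center=self.means[index],
            shape=self.covariances[index],
            n=self.settings.get("n", 0),
        )
        if coverage is not None:
            e = scale_to_coverage(e, coverage)
        return e


@dataclasses.dataclass(frozen=True)
class VolumeSummary:
    """Posterior summary of ellipsoid volume at a given coverage."""

    median: float
    iqr_25: float
    iqr_75: float
    coverage: float
    n_draws: int


@dataclasses.dataclass(frozen=True)
class OverlapPosterior:
    """Posterior overlap between two groups, directed both ways.

    Medians and equal-tailed 95% credible intervals of the directed
    percentages over paired posterior draws.
    """

    median_ab: float
    ci_ab: tuple[float, float]
    median_ba: float
    ci_ba: tuple[float, float]
    percents_ab: np.ndarray
    percents_ba: np.ndarray
    subdivision: int
    coverage: float

    @property
    def significant_ab(self) -> bool:
        return classify_overlap(self.median_ab)

    @property
    def significant_ba(self) -> bool:
        return classify_overlap(self.median_ba)


def _check_settings(iterations: int, burn_in: int, thin: int) -> None:
    if iterations <= 0 or burn_in < 0 or thin < 1:
        raise ValidationError(
            "sampler settings must satisfy iterations > 0, "
            "burn_in >= 0, thin >= 1"
        )
    if burn_in >= iterations:
        raise ValidationError(
            f"burn_in ({burn_in}) must be smaller than "
            f"iterations ({iterations})"
        )


def fit_posterior(
    data: np.ndarray,
    iterations: int = DEFAULT_ITERATIONS,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int = DEFAULT_THIN,
    seed: int | np.random.Generator | None = None,
    prior: NIWPrior | None = None,
) -> PosteriorDraws:
    """Gibbs-sample the posterior of a group's mean and covariance.

    Retains draw ``t`` when ``t > burn_in`` and ``(t - burn_in)`` is a
    multiple of ``thin``, giving ``floor((iterations - burn_in) / thin)``
    retained draws (200 under the defaults).  Reproducible for a fixed
    integer seed.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise InsufficientSampleError(
            f"expected an n x 3 matrix, got shape {data.shape}"
        )
    n = data.shape[0]
    if n < 4:
        raise InsufficientSampleError(
            f"insufficient sample: need at least 4 rows, got {n}"
        )
    _check_settings(iterations, burn_in, thin)
    prior = prior or NIWPrior()
    rng = np.random.default_rng(seed)

    xbar = data.mean(axis=0)
    kappa_n = prior.kappa + n
    post_mean = (prior.kappa * prior.mean + n * xbar) / kappa_n
    df_n = prior.df + n + 1

    n_retained = (iterations - burn_in) // thin
    means = np.empty((n_retained, 3))
    covs = np.empty((n_retained, 3, 3))

    sigma = np.cov(data, rowvar=False, ddof=1)
    k = 0
    for t in range(1, iterations + 1):
        # mu | Sigma, X
        L = np.linalg.cholesky(sigma / kappa_n)
        mu = post_mean + L @ rng.standard_normal(3)
        # Sigma | mu, X
        centered = data - mu
        scatter = centered.T @ centered
        dm = mu - prior.mean
        scale_n = prior.scale + scatter + prior.kappa * np.outer(dm, dm)
        sigma = stats.invwishart.rvs(df=df_n, scale=scale_n, random_state=rng)
        if t > burn_in and (t - burn_in) % thin == 0:
            means[k] = mu
            covs[k] = sigma
            k += 1

    settings = {
        "iterations": int(iterations),
        "burn_in": int(burn_in),
        "thin": int(thin),
        "n": int(n),
        "prior_kappa": float(prior.kappa),
        "prior_df": float(prior.df),
        "sampler": "conjugate NIW Gibbs",
    }
    return PosteriorDraws(means=means, covariances=covs, settings=settings)


def volume_posterior(
    draws: PosteriorDraws, coverage: float = SIGMA1_COVERAGE
) -> tuple[VolumeSummary, np.ndarray]:
    """Posterior distribution of ellipsoid volume at coverage ``p``.

    Each covariance draw is rescaled by the chi-square(3) quantile rule
    and its volume ``(4/3) pi sqrt(det)`` recorded; the summary holds the
    median and interquartile range (linear-interpolation quantiles).
    Returns the summary and the raw per-draw volumes.
    """
    if draws.n_draws == 0:
        raise ValidationError("empty draw set")
    if not 0.0 < coverage < 1.0:
        raise ValidationError(
            f"invalid coverage {coverage!r}: must lie in (0, 1)"
        )
    q = stats.chi2.ppf(coverage, df=3)
    sign, logdet = np.linalg.slogdet(draws.covariances)
    if np.any(sign <= 0):
        raise ValidationError("non-positive-definite covariance draw")
    volumes = 4.0 / 3.0 * np.pi * q**1.5 * np.exp(0.5 * logdet)
    lo, med, hi = np.quantile(volumes, [0.25, 0.5, 0.75])
    summary = VolumeSummary(
        median=float(med),
        iqr_25=float(lo),
        iqr_75=float(hi),
        coverage=float(coverage),
        n_draws=draws.n_draws,
    )
    return summary, volumes


def overlap_posterior(
    draws_a: PosteriorDraws,
    draws_b: PosteriorDraws,
    coverage: float = 0.75,
    subdivision: int = 4,
    max_draws: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> OverlapPosterior:
    """Posterior overlap between two groups from paired draws.

    For each retained draw index the coverage-``p`` ellipsoids of both
    groups are built and their mesh overlap computed; the directed
    percentages are summarized by the median and equal-tailed 95%
    credible interval.  ``max_draws`` subsamples draw indices (without
    replacement, seeded) to bound the mesh-overlap cost.
    """
    if draws_a.n_draws != draws_b.n_draws:
        raise PairingError(
            "pairing error: draw counts differ "
            f"({draws_a.n_draws} vs {draws_b.n_draws})"
        )
    indices = np.arange(draws_a.n_draws)
    if max_draws is not None and max_draws < len(indices):
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(indices, size=max_draws, replace=False))
    pct_ab = np.empty(len(indices))
    pct_ba = np.empty(len(indices))
    for out, idx in enumerate(indices):
        ea = draws_a.ellipsoid(idx, coverage=coverage)
        eb = draws_b.ellipsoid(idx, coverage=coverage)
        est = mesh_mod.overlap(ea, eb, subdivision=subdivision)
        pct_ab[out] = est.percent_of_first
        pct_ba[out] = est.percent_of_second
    lo_ab, med_ab, hi_ab = np.quantile(pct_ab, [0.025, 0.5, 0.975])
    lo_ba, med_ba, hi_ba = np.quantile(pct_ba, [0.025, 0.5, 0.975])
    return OverlapPosterior(
        median_ab=float(med_ab),
        ci_ab=(float(lo_ab), float(hi_ab)),
        median_ba=float(med_ba),
        ci_ba=(float(lo_ba), float(hi_ba)),
        percents_ab=pct_ab,
        percents_ba=pct_ba,
        subdivision=int(subdivision),
        coverage=float(coverage),
    )


def classify_overlap(percent: float) -> bool:
    """True when a directed overlap percentage counts as significant (>= 60%)."""
    if not 0.0 <= percent <= 100.0:
        raise ValidationError(
            f"overlap percent must lie in [0, 100], got {percent!r}"
        )
    return percent >= SIGNIFICANT_OVERLAP_PERCENT


def small_sample_bias_sim(
    n_values: Sequence[int],
    replicates: int,
    true_cov: np.ndarray,
    seed: int | None = None,
    iterations: int = 1_500,
    burn_in: int = 500,
    thin: int = 5,
    prior: NIWPrior | None = None,
):
    """Median relative bias of the posterior-median volume versus truth.

    For each sample size ``n``, ``replicates`` synthetic datasets are
    drawn from ``N(0, true_cov)``, the posterior fitted, and the relative
    error of the posterior-median 1-sigma volume against the true
    analytic volume recorded.  Returns a DataFrame with one row per
    ``n``: the median relative bias and the fraction of replicates that
    underestimated.  Shorter default chains than the headline fit keep
    replicated simulation affordable; the conjugate sampler mixes fast
    enough that this does not change the verdict.
    """
    import pandas as pd

    if replicates < 1:
        raise ValidationError(
            f"replicates must be positive, got {replicates}"
        )
    n_values = [int(n) for n in n_values]
    if any(n < 4 for n in n_values):
        raise ValidationError("every n must be at least 4")
    true_cov = np.asarray(true_cov, dtype=float)
    true_vol = sev(Ellipsoid(center=np.zeros(3), shape=true_cov))
    chol = np.linalg.cholesky(true_cov)
    root = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        rel = np.empty(replicates)
        for r in range(replicates):
            data = root.standard_normal((n, 3)) @ chol.T
            draws = fit_posterior(
                data,
                iterations=iterations,
                burn_in=burn_in,
                thin=thin,
                seed=root.integers(2**31 - 1),
                prior=prior,
            )
            summary, _ = volume_posterior(draws)
            rel[r] = (summary.median - true_vol) / true_vol
        rows.append(
            {
                "n": n,
                "median_rel_bias": float(np.median(rel)),
                "frac_underestimating": float(np.mean(rel < 0)),
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)
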