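"""Model/Results interface over the ellipsoid-niche machinery.

:class:`IsotopeNicheModel` wraps one group's trivariate isotope sample.
``fit()`` gives the analytic results (standard ellipsoid, SEV, SEV_C,
Layman ranges, Mardia's normality check); ``fit_bayes()`` runs the
conjugate Gibbs sampler and gives posterior volume summaries, with
pairwise overlap available between two Bayesian results objects.

    >>> model = IsotopeNicheModel.from_dataframe(table)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> bres = model.fit_bayes(seed=1)
    >>> bres.volume_summary(coverage=0.75).median
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bayes as bayes_mod
from . import geometry as geom
from . import prep
from .exceptions import ValidationError

__all__ = [
    "IsotopeNicheModel",
    "NicheResults",
    "BayesianNicheResults",
]


class IsotopeNicheModel:
    """Trivariate-normal niche model for one group of individuals.

    Parameters
    ----------
    endog : (n, 3) array_like
        Isotope values in (d13C, d15N, d34S) column order, already
        lipid-corrected where applicable.
    label : str, optional
        Group label carried into summaries.
    """

    def __init__(self, endog, label: str = ""):
        endog = np.asarray(endog, dtype=float)
        if endog.ndim != 2 or endog.shape[1] != 3:
            raise ValidationError(
                f"endog must be n x 3, got shape {endog.shape}"
            )
        self.endog = endog
        self.label = label
        self.nobs = endog.shape[0]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        columns=prep.ISOTOPE_COLUMNS,
        label: str = "",
    ) -> "IsotopeNicheModel":
        """Build a model from a DataFrame carrying the isotope columns."""
        missing = [c for c in columns if c not in data.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        return cls(data.loc[:, list(columns)].to_numpy(dtype=float), label=label)

    def fit(self) -> "NicheResults":
        """Analytic fit: standard ellipsoid plus univariate metrics."""
        ellipsoid = geom.ellipsoid_from_sample(self.endog)
        return NicheResults(self, ellipsoid)

    def fit_bayes(
        self,
        iterations: int = bayes_mod.DEFAULT_ITERATIONS,
        burn_in: int = bayes_mod.DEFAULT_BURN_IN,
        thin: int = bayes_mod.DEFAULT_THIN,
        seed=None,
        prior: bayes_mod.NIWPrior | None = None,
    ) -> "BayesianNicheResults":
        """Bayesian fit via the conjugate Normal-Inverse-Wishart sampler."""
        draws = bayes_mod.fit_posterior(
            self.endog,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            prior=prior,
        )
        return BayesianNicheResults(self, draws)


class NicheResults:
    """Analytic niche-ellipsoid results for one group."""

    def __init__(self, model: IsotopeNicheModel, ellipsoid: geom.Ellipsoid):
        self.model = model
        self.ellipsoid = ellipsoid
        self.nobs = model.nobs

    @property
    def center(self) -> np.ndarray:
        return self.ellipsoid.center

    @property
    def covariance(self) -> np.ndarray:
        return self.ellipsoid.shape

    @property
    def semi_axes(self) -> np.ndarray:
        return geom.semi_axes(self.ellipsoid)

    @property
    def sev(self) -> float:
        """Standard ellipsoid volume (1-sigma), permil^3."""
        return geom.sev(self.ellipsoid)

    @property
    def sev_c(self) -> float:
        """Small-sample corrected volume SEV * (n - 1)/(n - 3)."""
        return geom.sev_c(self.ellipsoid)

    def volume(self, coverage: float) -> float:
        """Ellipsoid volume rescaled to capture ``coverage`` of the data."""
        return geom.sev(geom.scale_to_coverage(self.ellipsoid, coverage))

    def layman_ranges(self) -> prep.LaymanRanges:
        return prep.layman_ranges(self.model.endog)

    def mardia(self, **kwargs) -> prep.MardiaResult:
        return prep.mardia_test(self.model.endog, **kwargs)

    def summary(self) -> str:
        a, b, c = self.semi_axes
        ranges = self.layman_ranges() if self.nobs >= 2 else None
        mardia = self.mardia() if self.nobs >= 5 else None
        label = self.model.label or "(unnamed group)"
        lines = [
            "Trivariate Isotope Niche (analytic)",
            "=" * 52,
            f"Group:          {label}",
            f"Observations:   {self.nobs}",
            f"Center (permil): d13C {self.center[0]:8.3f}   "
            f"d15N {self.center[1]:7.3f}   d34S {self.center[2]:7.3f}",
            f"Semi-axes:      a {a:.3f}  b {b:.3f}  c {c:.3f}",
            f"SEV:            {self.sev:.4f} permil^3",
            f"SEV_C (n={self.nobs}):   {self.sev_c:.4f} permil^3",
        ]
        if ranges is not None:
            lines.append(
                f"Ranges:         CR {ranges.cr:.3f}  NR {ranges.nr:.3f}  "
                f"SR {ranges.sr:.3f}"
            )
        if mardia is not None:
            verdict = "normal" if mardia.normal else "non-normal"
            lines.append(
                f"Mardia:         skew p={mardia.skew_p:.3f}  "
                f"kurt p={mardia.kurt_p:.3f}  [{verdict}]"
            )
        return "\n".join(lines)


class BayesianNicheResults:
    """Posterior niche-ellipsoid results for one group."""

    def __init__(
        self, model: IsotopeNicheModel, draws: bayes_mod.PosteriorDraws
    ):
        self.model = model
        self.draws = draws
        self.nobs = model.nobs

    def volume_summary(
        self, coverage: float = geom.SIGMA1_COVERAGE
    ) -> bayes_mod.VolumeSummary:
        summary, _ = bayes_mod.volume_posterior(self.draws, coverage=coverage)
        return summary

    def volume_draws(
        self, coverage: float = geom.SIGMA1_COVERAGE
    ) -> np.ndarray:
        _, volumes = bayes_mod.volume_posterior(self.draws, coverage=coverage)
        return volumes

    def overlap(
        self,
        other: "BayesianNicheResults",
        coverage: float = 0.75,
        subdivision: int = 4,
        max_draws: int | None = None,
        seed=None,
    ) -> bayes_mod.OverlapPosterior:
        """Posterior pairwise overlap with another group's results."""
        return bayes_mod.overlap_posterior(
            self.draws,
            other.draws,
            coverage=coverage,
            subdivision=subdivision,
            max_draws=max_draws,
            seed=seed,
        )

    def summary(self, coverage: float = 0.75) -> str:
        vs = self.volume_summary(coverage=coverage)
        s = self.draws.settings
        label = self.model.label or "(unnamed group)"
        return "\n".join(
            [
                "Trivariate Isotope Niche (Bayesian)",
                "=" * 52,
                f"Group:          {label}",
                f"Observations:   {self.nobs}",
                f"Sampler:        {s.get('sampler', 'Gibbs')} — "
                f"{s['iterations']} iterations, burn-in {s['burn_in']}, "
                f"thin {s['thin']} ({self.draws.n_draws} draws)",
                f"EV_B ({coverage:.0%}):     median {vs.median:.4f} permil^3   "
                f"IQR [{vs.iqr_25:.4f}, {vs.iqr_75:.4f}]",
            ]
        )
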