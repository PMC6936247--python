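"""Posterior estimation of niche ellipsoid volume and overlap."""

import numpy as np
import pytest
from scipy import stats

from isoniche import (
    Ellipsoid,
    InsufficientSampleError,
    NIWPrior,
    PairingError,
    PosteriorDraws,
    SIGMA1_COVERAGE,
    ValidationError,
    classify_overlap,
    ellipsoid_from_sample,
    fit_posterior,
    overlap_posterior,
    sev,
    small_sample_bias_sim,
    volume_posterior,
)

FAST = dict(iterations=1_000, burn_in=500, thin=5)  # 100 retained draws


def simulate(rng, mean, cov, n):
    return rng.multivariate_normal(mean, cov, size=n)


def constant_draws(cov, k=50, mean=None):
    mean = np.zeros(3) if mean is None else np.asarray(mean, float)
    return PosteriorDraws(
        means=np.tile(mean, (k, 1)),
        covariances=np.tile(cov, (k, 1, 1)),
        settings={"n": 0},
    )


class TestFitPosterior:
    def test_retained_draw_arithmetic(self, rng):
        data = simulate(rng, np.zeros(3), np.eye(3), 30)
        draws = fit_posterior(data, iterations=1_000, burn_in=400, thin=12, seed=1)
        assert draws.n_draws == (1_000 - 400) // 12

    def test_deterministic_under_seed(self, rng):
        data = simulate(rng, np.zeros(3), np.eye(3), 20)
        a = fit_posterior(data, seed=42, **FAST)
        b = fit_posterior(data, seed=42, **FAST)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.covariances, b.covariances)

    def test_parameter_recovery(self, rng):
        # Componentwise, the posterior mean should sit within 3 posterior
        # SDs of the generating mean in the vast majority of replicates.
        mean = np.array([-16.0, 12.5, 19.0])
        cov = np.array([[0.5, 0.1, 0.0], [0.1, 0.3, 0.05], [0.0, 0.05, 0.4]])
        within = 0
        for rep in range(5):
            data = simulate(rng, mean, cov, 500)
            draws = fit_posterior(data, seed=3 + rep, **FAST)
            post_mean = draws.means.mean(axis=0)
            post_sd = draws.means.std(axis=0)
            within += int(np.sum(np.abs(post_mean - mean) < 3 * post_sd))
        assert within >= 13  # of 15 component checks

    def test_every_covariance_draw_spd(self, rng):
        data = simulate(rng, np.zeros(3), np.diag([0.5, 0.2, 0.3]), 8)
        draws = fit_posterior(data, seed=4, **FAST)
        for cov in draws.covariances:
            np.linalg.cholesky(cov)  # raises if not SPD

    def test_insufficient_data(self):
        with pytest.raises(InsufficientSampleError):
            fit_posterior(np.zeros((3, 3)), **FAST)

    @pytest.mark.parametrize(
        "settings",
        [
            dict(iterations=100, burn_in=100, thin=1),
            dict(iterations=100, burn_in=200, thin=1),
            dict(iterations=100, burn_in=10, thin=0),
        ],
    )
    def test_invalid_settings(self, settings, rng):
        data = simulate(rng, np.zeros(3), np.eye(3), 10)
        with pytest.raises(ValidationError):
            fit_posterior(data, **settings)

    def test_invalid_prior(self):
        with pytest.raises(ValidationError):
            NIWPrior(kappa=-1.0)
        with pytest.raises(ValidationError):
            NIWPrior(df=-1.0)


class TestVolumePosterior:
    def test_degenerate_posterior_unit_covariance(self):
        draws = constant_draws(np.eye(3))
        summary, volumes = volume_posterior(draws, coverage=SIGMA1_COVERAGE)
        np.testing.assert_allclose(volumes, 4 * np.pi / 3, rtol=1e-12)
        assert summary.iqr_75 - summary.iqr_25 == pytest.approx(0.0, abs=1e-12)

    def test_coverage_scaling_law(self, rng):
        data = simulate(rng, np.zeros(3), np.eye(3), 25)
        draws = fit_posterior(data, seed=5, **FAST)
        _, base = volume_posterior(draws, coverage=SIGMA1_COVERAGE)
        _, scaled = volume_posterior(draws, coverage=0.75)
        q = stats.chi2.ppf(0.75, df=3)
        np.testing.assert_allclose(scaled, base * q**1.5, rtol=1e-10)

    def test_posterior_median_consistent_with_sample_sev(self, rng):
        data = simulate(rng, np.zeros(3), np.diag([0.6, 0.3, 0.4]), 500)
        draws = fit_posterior(data, seed=6, **FAST)
        summary, _ = volume_posterior(draws)
        sample_sev = sev(ellipsoid_from_sample(data))
        assert summary.median == pytest.approx(sample_sev, rel=0.05)

    def test_posterior_contraction_with_n(self, rng):
        # Nested subsets of one dataset: relative volume uncertainty
        # (SD of log volume) must shrink as more data are used.
        cov = np.diag([0.5, 0.2, 0.3])
        data = simulate(rng, np.zeros(3), cov, 250)
        spreads = []
        for n in (10, 50, 250):
            draws = fit_posterior(data[:n], seed=7, **FAST)
            _, volumes = volume_posterior(draws)
            spreads.append(np.std(np.log(volumes)))
        assert spreads[0] > spreads[1] > spreads[2]

    def test_summary_ordering_invariant(self, rng):
        data = simulate(rng, np.zeros(3), np.eye(3), 15)
        draws = fit_posterior(data, seed=8, **FAST)
        summary, _ = volume_posterior(draws, coverage=0.75)
        assert summary.iqr_25 <= summary.median <= summary.iqr_75
        assert summary.iqr_25 > 0

    def test_credible_interval_calibration(self, rng):
        # Equal-tailed 95% intervals for the 1-sigma volume should cover
        # the true SEV about 95 times in 100 replicates at n = 30.
        cov = np.diag([0.5, 0.25, 0.35])
        true_vol = sev(Ellipsoid(center=np.zeros(3), shape=cov))
        chol = np.linalg.cholesky(cov)
        hits = 0
        for _ in range(100):
            data = rng.standard_normal((30, 3)) @ chol.T
            draws = fit_posterior(
                data, seed=int(rng.integers(2**31 - 1)), **FAST
            )
            _, volumes = volume_posterior(draws)
            lo, hi = np.quantile(volumes, [0.025, 0.975])
            hits += lo <= true_vol <= hi
        assert 90 <= hits <= 99


class TestOverlapPosterior:
    def test_group_against_itself(self, rng):
        data = simulate(rng, np.zeros(3), np.eye(3), 20)
        draws = fit_posterior(data, iterations=260, burn_in=200, thin=3, seed=9)
        post = overlap_posterior(draws, draws, coverage=0.75, subdivision=1)
        assert post.median_ab == pytest.approx(100.0, abs=1e-9)
        assert post.ci_ab[1] - post.ci_ab[0] == pytest.approx(0.0, abs=1e-9)

    def test_far_separated_groups(self, rng):
        a = simulate(rng, np.zeros(3), np.eye(3), 20)
        b = simulate(rng, np.array([100.0, 0, 0]), np.eye(3), 20)
        settings = dict(iterations=260, burn_in=200, thin=3)
        da = fit_posterior(a, seed=10, **settings)
        db = fit_posterior(b, seed=11, **settings)
        post = overlap_posterior(da, db, coverage=0.75, subdivision=1)
        assert post.median_ab == 0.0
        assert post.median_ba == 0.0
        assert not post.significant_ab

    def test_same_distribution_recovery(self, rng):
        # Two groups simulated from one normal should overlap heavily.
        cov = np.diag([0.5, 0.3, 0.4])
        a = simulate(rng, np.zeros(3), cov, 50)
        b = simulate(rng, np.zeros(3), cov, 50)
        settings = dict(iterations=400, burn_in=300, thin=4)
        da = fit_posterior(a, seed=12, **settings)
        db = fit_posterior(b, seed=13, **settings)
        post = overlap_posterior(da, db, coverage=0.75, subdivision=1)
        assert post.median_ab > 60.0
        assert post.median_ba > 60.0

    def test_pairing_error(self, rng):
        data = simulate(rng, np.zeros(3), np.eye(3), 15)
        da = fit_posterior(data, iterations=300, burn_in=200, thin=2, seed=1)
        db = fit_posterior(data, iterations=300, burn_in=200, thin=4, seed=1)
        with pytest.raises(PairingError):
            overlap_posterior(da, db)

    def test_max_draws_subsamples(self, rng):
        data = simulate(rng, np.zeros(3), np.eye(3), 15)
        draws = fit_posterior(data, iterations=300, burn_in=200, thin=2, seed=1)
        post = overlap_posterior(
            draws, draws, subdivision=0, max_draws=10, seed=2
        )
        assert len(post.percents_ab) == 10


class TestClassifyOverlap:
    @pytest.mark.parametrize(
        "percent,expected",
        [(63.0, True), (74.0, True), (60.0, True), (59.99, False), (0.0, False)],
    )
    def test_threshold(self, percent, expected):
        assert classify_overlap(percent) is expected

    @pytest.mark.parametrize("percent", [-1.0, 100.5])
    def test_out_of_range(self, percent):
        with pytest.raises(ValidationError):
            classify_overlap(percent)


class TestSmallSampleBias:
    def test_bias_negative_at_small_n_and_vanishing_at_large_n(self):
        table = small_sample_bias_sim(
            [5, 100],
            replicates=60,
            true_cov=np.eye(3),
            seed=14,
            iterations=600,
            burn_in=200,
            thin=4,
        )
        small = table.loc[table.n == 5, "median_rel_bias"].item()
        large = table.loc[table.n == 100, "median_rel_bias"].item()
        assert small < 0
        assert abs(large) < 0.05

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValidationError):
            small_sample_bias_sim([5], replicates=0, true_cov=np.eye(3))

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            small_sample_bias_sim([3], replicates=10, true_cov=np.eye(3))
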