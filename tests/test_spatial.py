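"""Distance, correlation, constrained-field and kriging machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duckharvest import spatial


class TestHaversine:
    def test_zero_for_coincident_points(self):
        assert spatial.haversine_distance((45.5, -70.5), (45.5, -70.5)) == 0.0

    def test_one_degree_of_latitude_at_equator(self):
        # R * 1 deg * pi / 180 with R = 6371 km
        assert spatial.haversine_distance((0, 0), (1, 0)) == pytest.approx(111.195, abs=1e-3)

    def test_antipodal_points(self):
        assert spatial.haversine_distance((0, 0), (0, 180)) == pytest.approx(20015.1, abs=0.1)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            spatial.haversine_distance((91, 0), (0, 0))

    def test_distance_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(42, 57, 12), rng.uniform(-80, -60, 12)])
        d = spatial.distance_matrix(pts)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        # triangle inequality on all triples
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_matrix_matches_pairwise(self):
        pts = np.array([[45.0, -70.0], [50.0, -65.0], [42.0, -79.0]])
        d = spatial.distance_matrix(pts)
        for i in range(3):
            for j in range(3):
                assert d[i, j] == pytest.approx(
                    spatial.haversine_distance(pts[i], pts[j]), abs=1e-9)


class TestExpCorrelation:
    def test_unit_at_zero_distance(self):
        assert spatial.exp_correlation(0.0, 0.01) == 1.0

    def test_known_value(self):
        assert spatial.exp_correlation(100.0, 0.01) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_vanishes_at_large_theta(self):
        assert spatial.exp_correlation(100.0, 50.0) < 1e-100

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            spatial.exp_correlation(10.0, 0.0)

    # theta * d kept below ~500 so exp(-theta*d) stays above underflow
    @given(st.floats(1.0, 3000.0), st.floats(1e-5, 0.05), st.floats(1.01, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_distance_and_theta(self, d, theta, mult):
        assert spatial.exp_correlation(d * mult, theta) < spatial.exp_correlation(d, theta)
        assert spatial.exp_correlation(d, theta * mult) < spatial.exp_correlation(d, theta)


class TestRangeAndPriorBounds:
    def test_effective_range_known_value(self):
        assert spatial.effective_range(0.003) == pytest.approx(998.577, abs=1e-2)
        assert spatial.effective_range_approx(0.003) == pytest.approx(1000.0, abs=1e-9)

    def test_reported_fit_range_inverts(self):
        theta = -np.log(0.05) / 462.0
        assert spatial.effective_range(theta) == pytest.approx(462.0, rel=1e-12)

    def test_prior_bounds_from_study_distances(self):
        lower, upper = spatial.theta_prior_bounds(2756.0, 63.0)
        assert lower == pytest.approx(-np.log(0.99) / 2756.0, abs=1e-9)
        assert upper == pytest.approx(-np.log(0.01) / 63.0, abs=1e-9)
        assert lower < upper

    def test_round_trips_exact(self):
        # bounds and effective range are exact inverses of the correlation
        lower, upper = spatial.theta_prior_bounds(2756.0, 63.0)
        assert spatial.exp_correlation(2756.0, lower) == pytest.approx(0.99, abs=1e-12)
        assert spatial.exp_correlation(63.0, upper) == pytest.approx(0.01, abs=1e-12)
        theta = 0.007
        assert spatial.exp_correlation(spatial.effective_range(theta), theta) == \
            pytest.approx(0.05, abs=1e-12)

    def test_invalid_distances_rejected(self):
        with pytest.raises(ValueError):
            spatial.theta_prior_bounds(63.0, 2756.0)
        with pytest.raises(ValueError):
            spatial.theta_prior_bounds(100.0, 0.0)


class TestConstrainedField:
    def test_draws_sum_to_zero(self):
        pts = np.column_stack([np.linspace(43, 52, 10), np.linspace(-75, -66, 10)])
        d = spatial.distance_matrix(pts)
        z = spatial.sample_constrained_field(d, 0.005, 0.8, 200, seed=0)
        assert np.max(np.abs(z.sum(axis=1))) < 1e-10

    def test_single_block_is_degenerate_zero(self):
        z = spatial.sample_constrained_field(np.zeros((1, 1)), 0.01, 1.0, 5, seed=0)
        assert np.all(z == 0)

    def test_reproducible_under_seed(self):
        d = spatial.distance_matrix(np.array([[45, -70], [46, -71], [47, -69.0]]))
        z1 = spatial.sample_constrained_field(d, 0.01, 0.5, 10, seed=42)
        z2 = spatial.sample_constrained_field(d, 0.01, 0.5, 10, seed=42)
        np.testing.assert_array_equal(z1, z2)

    def test_empirical_covariance_matches_projected_covariance(self):
        # oracle: P (sigma^2 K) P with P the centering projector
        pts = np.array([[44, -70], [45, -70], [46, -71], [48, -68], [50, -75.0]])
        d = spatial.distance_matrix(pts)
        sigma, theta = 0.7, 0.004
        K = spatial.exp_correlation(d, theta)
        P = np.eye(5) - np.ones((5, 5)) / 5
        target = P @ (sigma ** 2 * K) @ P
        z = spatial.sample_constrained_field(d, theta, sigma, 10_000, seed=7)
        emp = np.cov(z.T, ddof=1)
        assert np.max(np.abs(emp - target)) < 0.05  # Monte-Carlo tolerance

    def test_projection_idempotent(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=20)
        once = z - z.mean()
        twice = once - once.mean()
        np.testing.assert_allclose(once, twice, atol=1e-15)


class TestConditionalPredict:
    def test_coincident_block_reproduces_observed_value(self):
        pts = np.array([[45, -70], [46, -71], [48, -69.0]])
        z = np.array([0.4, -0.1, -0.3])
        mean, var = spatial.conditional_predict(z, pts, pts[1:2], 0.005, 0.6)
        assert mean[0] == pytest.approx(z[1], abs=1e-5)
        assert var[0] == pytest.approx(0.0, abs=1e-5)

    def test_distant_block_reverts_to_prior(self):
        pts = np.array([[45, -70], [46, -71.0]])
        z = np.array([0.4, -0.4])
        far = np.array([[56.0, -100.0]])
        mean, var = spatial.conditional_predict(z, pts, far, 0.05, 0.6)
        assert abs(mean[0]) < 1e-6
        assert var[0] == pytest.approx(0.36, rel=1e-3)

    def test_three_block_toy_matches_hand_solve(self):
        pts = np.array([[45.0, -70.0], [45.0, -69.0], [45.5, -69.5]])
        theta, sigma = 0.01, 0.5
        z = np.array([0.3, -0.2])
        d = spatial.distance_matrix(pts)
        K = spatial.exp_correlation(d[:2, :2], theta)
        kstar = spatial.exp_correlation(d[:2, 2], theta)
        expected_mean = kstar @ np.linalg.solve(K, z)
        expected_var = sigma ** 2 * (1 - kstar @ np.linalg.solve(K, kstar))
        mean, var = spatial.conditional_predict(z, pts[:2], pts[2:], theta, sigma)
        assert mean[0] == pytest.approx(expected_mean, rel=1e-6)
        assert var[0] == pytest.approx(expected_var, rel=1e-3)

    def test_vectorized_over_draws(self):
        pts = np.array([[45, -70], [46, -71], [48, -69.0]])
        zdraws = np.random.default_rng(0).normal(size=(4, 3))
        thetas = np.array([0.004, 0.004, 0.01, 0.01])
        sig = np.array([0.5, 0.6, 0.5, 0.6])
        mean, var = spatial.conditional_predict(zdraws, pts, np.array([[47.0, -70.0]]),
                                                thetas, sig)
        assert mean.shape == (4, 1) and var.shape == (4, 1)
        m0, v0 = spatial.conditional_predict(zdraws[2], pts, np.array([[47.0, -70.0]]),
                                             0.01, 0.5)
        assert mean[2, 0] == pytest.approx(m0[0], rel=1e-12)
        assert var[2, 0] == pytest.approx(v0[0], rel=1e-12)
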