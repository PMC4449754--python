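"""Model spec construction, likelihood, diagnostics, and prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from duckharvest import model, simulate
from duckharvest.model import build_spec, log_likelihood, predict_probability, split_rhat


def tiny_cube(N, y, x=None):
    """One-block cube with given (year, age, bandtype) count arrays."""
    from duckharvest.ingest import CountCube

    N = np.asarray(N)[None]
    y = np.asarray(y)[None]
    x = np.zeros_like(y) if x is None else np.asarray(x)[None]
    years = list(range(1970, 1970 + N.shape[1]))
    return CountCube(N=N, y=y, x=x, blocks=[(45, -70)], years=years,
                     ages=("juvenile", "adult"), band_types=("avise", "tollfree"))


def covariates_for(years):
    return simulate.simulate_covariates(years, seed=1, changepoint=years[len(years) // 2])


class TestBuildSpec:
    def test_roles_select_trials_and_successes(self):
        truth = simulate.TruthConfig(n_blocks=6, years=(1970, 1975), changepoint=1973, seed=1)
        cube, rec = simulate.simulate_cube(truth)
        rspec = build_spec(cube, rec["covariates"], "recovery")
        assert rspec.trials.sum() == cube.N.sum()
        assert rspec.successes.sum() == cube.y.sum()
        cspec = build_spec(cube, rec["covariates"], "canada")
        assert cspec.trials.sum() == cube.y.sum()
        assert cspec.successes.sum() == cube.x.sum()

    def test_zero_variance_covariate_rejected(self):
        truth = simulate.TruthConfig(n_blocks=4, years=(1970, 1975), changepoint=1990, seed=1)
        cube, rec = simulate.simulate_cube(truth)  # regulation never flips
        with pytest.raises(ValueError, match="zero variance"):
            build_spec(cube, rec["covariates"], "recovery")

    def test_all_zero_trials_rejected(self):
        cube = tiny_cube(np.zeros((3, 2, 2)), np.zeros((3, 2, 2)))
        cov = covariates_for(cube.years)
        with pytest.raises(ValueError, match="nothing to fit"):
            build_spec(cube, cov, "recovery")

    def test_covariate_scaling_stored(self):
        truth = simulate.TruthConfig(n_blocks=6, years=(1970, 1975), changepoint=1973, seed=1)
        cube, rec = simulate.simulate_cube(truth)
        spec = build_spec(cube, rec["covariates"], "recovery")
        raw = rec["covariates"].set_index("year").loc[cube.years, list(spec.covariate_names)]
        np.testing.assert_allclose(spec.X * spec.cov_sds + spec.cov_means,
                                   raw.to_numpy(), rtol=1e-12)


from conftest import brute_force_loglik  # noqa: E402


class TestLogLikelihood:
    def test_empty_spec_gives_zero(self):
        cube = tiny_cube(np.zeros((3, 2, 2)), np.zeros((3, 2, 2)))
        spec = build_spec(cube, covariates_for(cube.years), "recovery", allow_empty=True)
        params = {"alpha": np.zeros((2, 2)), "beta": np.zeros((3, 2))}
        assert log_likelihood(params, spec) == 0.0

    def test_single_cell_hand_value(self):
        # trials=2, successes=1, linear predictor 0 -> ln(C(2,1) * 0.25) = ln(0.5)
        N = np.zeros((3, 2, 2)); y = np.zeros((3, 2, 2))
        N[1, 0, 0], y[1, 0, 0] = 2, 1
        spec = build_spec(tiny_cube(N, y), covariates_for(range(1970, 1973)), "recovery")
        params = {"alpha": np.zeros((2, 2)), "beta": np.zeros((3, 2))}
        assert log_likelihood(params, spec) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_brute_force_on_random_specs(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            truth = simulate.TruthConfig(
                n_blocks=int(rng.integers(2, 15)), years=(1970, 1974),
                changepoint=1972, seed=int(rng.integers(2 ** 31)))
            cube, rec = simulate.simulate_cube(truth)
            spec = build_spec(cube, rec["covariates"], "recovery")
            params = {
                "alpha": rng.normal(-2, 0.5, (2, 2)), "beta": rng.normal(0, 0.3, (3, 2)),
                "z": rng.normal(0, 0.4, spec.n_blocks), "eps": rng.normal(0, 0.2, spec.n_by),
            }
            assert log_likelihood(params, spec) == pytest.approx(
                brute_force_loglik(params, spec), abs=1e-8)

    def test_non_finite_params_rejected(self):
        N = np.ones((3, 2, 2)); y = np.zeros((3, 2, 2))
        spec = build_spec(tiny_cube(N, y), covariates_for(range(1970, 1973)), "recovery")
        with pytest.raises(ValueError, match="non-finite"):
            log_likelihood({"alpha": np.full((2, 2), np.nan), "beta": np.zeros((3, 2))}, spec)


class TestSplitRhat:
    def test_iid_chains_give_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 10_000))
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1e-3, 500), 10 + rng.normal(0, 1e-3, 500)])
        assert split_rhat(chains) > 10

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.random.default_rng(0).normal(size=(1, 100)))

    def test_constant_chains_give_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero within-chain variance"):
            assert np.isnan(split_rhat(np.ones((2, 100))))

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = np.cumsum(rng.normal(size=(4, 400)), axis=1) * 0.05 + rng.normal(size=(4, 400))
        ours = split_rhat(chains)
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0], method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestPosteriorDraws:
    def test_field_sums_to_zero_every_draw(self, spatial_fit):
        *_, draws = spatial_fit
        z = draws.stacked("z")
        assert np.max(np.abs(z.sum(axis=1))) < 1e-6

    def test_theta_within_prior_support(self, spatial_fit):
        *_, spec, draws = spatial_fit
        th = draws.stacked("theta")
        lo, hi = spec.theta_bounds
        assert np.all(th >= lo) and np.all(th <= hi)

    def test_sigma_z_concentrates_near_zero_without_spatial_truth(self, nonspatial_fit):
        *_, draws = nonspatial_fit
        assert np.median(draws.stacked("sigma_z")) < 0.15


class TestPredictProbability:
    def test_fitted_block_matches_own_linear_predictor(self, spatial_fit):
        *_, spec, draws = spatial_fit
        year, age, bt = spec.years[3], "juvenile", spec.band_types[0]
        p = predict_probability(draws, spec, year, age, bt, blocks=[0, 5])
        a, b, t = 0, 0, 3
        lin = (draws.stacked("alpha")[:, a, b]
               + draws.stacked("beta")[:, :, a] @ spec.X[t])
        for j, blk in enumerate((0, 5)):
            np.testing.assert_allclose(
                p[:, j], expit(lin + draws.stacked("z")[:, blk]), rtol=1e-12)

    def test_unknown_age_or_band_type_rejected(self, spatial_fit):
        *_, spec, draws = spatial_fit
        with pytest.raises(ValueError, match="age"):
            predict_probability(draws, spec, spec.years[0], "hatchling", spec.band_types[0])
        with pytest.raises(ValueError, match="band type"):
            predict_probability(draws, spec, spec.years[0], "juvenile", "laser")

    def test_integrated_heterogeneity_widens_spread(self, spatial_fit):
        *_, spec, draws = spatial_fit
        year, age, bt = spec.years[2], "adult", spec.band_types[0]
        p0 = predict_probability(draws, spec, year, age, bt, blocks=[0])
        p1 = predict_probability(draws, spec, year, age, bt, blocks=[0],
                                 heterogeneity="integrate",
                                 rng=np.random.default_rng(0))
        assert p1.std() > p0.std()

    def test_new_block_prediction_between_prior_and_interpolation(self, spatial_fit):
        *_, spec, draws = spatial_fit
        # a centroid far outside the grid reverts toward the block average
        far = np.array([[70.0, -140.0]])
        p_far = predict_probability(draws, spec, spec.years[0], "juvenile",
                                    spec.band_types[0], new_coords=far)
        lin = (draws.stacked("alpha")[:, 0, 0]
               + draws.stacked("beta")[:, :, 0] @ spec.X[0])
        # small theta draws keep a little correlation even at this distance
        np.testing.assert_allclose(p_far[:, 0], expit(lin), rtol=1e-3)
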