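"""Shared fixtures.

MCMC fits are expensive, so they are session-scoped and shared between the
unit tests and the acceptance suite.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from duckharvest import model, simulate


def brute_force_loglik(params, spec):
    """Independent oracle: per-cell binomial pmf summed in a python loop."""
    alpha, beta = params["alpha"], params["beta"]
    z = params.get("z", np.zeros(spec.n_blocks))
    eps = params.get("eps", np.zeros(spec.n_by))
    total = 0.0
    for c in range(spec.trials.size):
        n, y = int(spec.trials[c]), int(spec.successes[c])
        mu = (alpha[spec.ia[c], spec.ig[c]]
              + sum(beta[k, spec.ia[c]] * spec.X[spec.it[c], k] for k in range(spec.n_cov))
              + z[spec.ib[c]] + eps[spec.iby[c]])
        p = 1.0 / (1.0 + math.exp(-mu))
        total += math.log(math.comb(n, y)) + y * math.log(p) + (n - y) * math.log1p(-p)
    return total


def small_truth(**overrides) -> simulate.TruthConfig:
    """30 blocks x 10 years x 2 band types; changepoint mid-span."""
    kw = dict(n_blocks=30, years=(1970, 1979), changepoint=1975, seed=11)
    kw.update(overrides)
    return simulate.TruthConfig(**kw)


def fit_scenario(truth: simulate.TruthConfig, role: str = "recovery",
                 n_chains: int = 2, n_warmup: int = 200, n_iter: int = 300,
                 seed: int = 5, data_seed=None):
    cube, rec = simulate.simulate_cube(truth, seed=data_seed)
    spec = model.build_spec(cube, rec["covariates"], role)
    draws = model.fit(spec, n_chains=n_chains, n_warmup=n_warmup,
                      n_iter=n_iter, seed=seed)
    return cube, rec, spec, draws


@pytest.fixture(scope="session")
def strong_fit():
    """Recovery fit of the reference synthetic study: 50 blocks x 20 years,
    2 band types, sigma_Z = 0.5, 500 km effective range, sigma_e = 0.3,
    juvenile effort slope 0.2; 4 chains x 500 iterations (half warmup)."""
    truth = simulate.TruthConfig()
    cube, rec = simulate.simulate_cube(truth)
    spec = model.build_spec(cube, rec["covariates"], "recovery")
    draws = model.fit(spec, n_chains=4, n_warmup=250, n_iter=500, seed=0)
    return cube, rec, spec, draws


@pytest.fixture(scope="session")
def spatial_fit():
    """Small scenario with strong spatial signal (sigma_Z = 0.8)."""
    return fit_scenario(small_truth(sigma_z=0.8, seed=21), seed=22)


@pytest.fixture(scope="session")
def nonspatial_fit():
    """Same scenario with no spatial field (sigma_Z = 0)."""
    return fit_scenario(small_truth(sigma_z=0.0, seed=21), seed=23)


@pytest.fixture(scope="session")
def identity_fits():
    """No-temporal-change scenario: one band type (no rollout), all
    covariate slopes zero, P_CAN near a flat 0.5; recovery and canada
    submodels fitted on the same grid.  Release intensity is high and the
    span long so that slope-estimation noise is negligible next to the
    identity being checked."""
    truth = simulate.TruthConfig(
        n_blocks=30, years=(1970, 1989), changepoint=1980,
        band_types=("avise",), alpha=np.array([[-2.3], [-2.5]]),
        beta=np.zeros((3, 2)), sigma_e=0.2,
        canada_beta=np.zeros((3, 2)), canada_alpha=np.zeros((2, 1)),
        canada_sigma_z=0.3, canada_sigma_e=0.3,
        mean_releases=(300.0, 150.0), seed=31,
    )
    cube, rec = simulate.simulate_cube(truth)
    rspec = model.build_spec(cube, rec["covariates"], "recovery")
    rdraws = model.fit(rspec, n_chains=2, n_warmup=200, n_iter=300, seed=32)
    cspec = model.build_spec(cube, rec["covariates"], "canada")
    cdraws = model.fit(cspec, n_chains=2, n_warmup=200, n_iter=300, seed=33)
    return cube, rec, rdraws, cdraws
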