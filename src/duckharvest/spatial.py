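"""Geometry and Gaussian-random-field machinery for 1-degree banding blocks.

Distances between block centroids are great-circle (haversine) distances in
km.  Spatial dependence uses the exponential correlation function
``rho(d) = exp(-theta * d)`` with decay rate ``theta`` per km; the effective
range is the distance at which correlation drops below 0.05.  The spatial
random effect is a zero-mean Gaussian field constrained to sum to zero
across blocks, which separates it from the intercepts.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, helmert

EARTH_RADIUS_KM = 6371.0

#: correlation levels used to anchor the range-parameter prior and the
#: effective range (prior bounds from the max/min pairwise distances).
_CORR_AT_DMAX = 0.99
_CORR_AT_DMIN = 0.01
_CORR_EFFECTIVE = 0.05

DEFAULT_JITTER = 1e-9


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.abs(lat) <= 90.0) and np.all(np.abs(lon) <= 180.0)):
        raise ValueError("coordinates outside [-90, 90] x [-180, 180]")
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("non-finite coordinates")


def haversine_distance(p1, p2) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    lat1, lon1 = (float(v) for v in p1)
    lat2, lon2 = (float(v) for v in p2)
    _check_coords(np.array([lat1, lat2]), np.array([lon1, lon2]))
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def distance_matrix(centroids: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between (lat, lon) centroids.

    Parameters
    ----------
    centroids : (n, 2) array of latitude, longitude in degrees.

    Returns
    -------
    (n, n) symmetric matrix with zero diagonal.
    """
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("centroids must be an (n, 2) array of lat, lon")
    _check_coords(c[:, 0], c[:, 1])
    phi = np.radians(c[:, 0])[:, None]
    lmb = np.radians(c[:, 1])[:, None]
    a = (
        np.sin((phi - phi.T) / 2.0) ** 2
        + np.cos(phi) * np.cos(phi.T) * np.sin((lmb - lmb.T) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def exp_correlation(d, theta: float) -> np.ndarray:
    """Exponential correlation ``exp(-theta * d)`` for distances ``d`` in km."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    k = np.exp(-theta * d)
    if k.ndim == 2 and k.shape[0] == k.shape[1]:
        np.fill_diagonal(k, 1.0)
    return k


def effective_range(theta: float) -> float:
    """Distance (km) at which correlation falls to 0.05: ``-ln(0.05) / theta``."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return -np.log(_CORR_EFFECTIVE) / theta


def effective_range_approx(theta: float) -> float:
    """The common ``3 / theta`` rule-of-thumb for the effective range."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    return 3.0 / theta


def theta_prior_bounds(d_max: float, d_min: float) -> tuple[float, float]:
    """Uniform-prior bounds for the decay rate from the distance matrix.

    The lower bound makes the two most distant blocks correlated at 0.99;
    the upper bound makes the two closest blocks correlated at 0.01.
    """
    if not (0 < d_min <= d_max):  # equality: a two-block grid
        raise ValueError("require 0 < d_min <= d_max")
    lower = -np.log(_CORR_AT_DMAX) / d_max
    upper = -np.log(_CORR_AT_DMIN) / d_min
    return float(lower), float(upper)


def sum_to_zero_basis(n: int) -> np.ndarray:
    """Orthonormal (n, n-1) basis of the sum-to-zero subspace of R^n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.zeros((1, 0))
    return helmert(n, full=False).T  # rows of helmert are orthonormal, ⟂ 1


def _chol_psd(mat: np.ndarray, jitter: float = DEFAULT_JITTER) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    try:
        return np.linalg.cholesky(m + jitter * np.eye(m.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"correlation matrix not positive definite after jitter {jitter:g}; "
            "check theta and the block grid"
        ) from exc


def sample_constrained_field(
    D: np.ndarray,
    theta: float,
    sigma_z: float,
    n_draws: int,
    seed=None,
    jitter: float = DEFAULT_JITTER,
) -> np.ndarray:
    """Draw sum-to-zero spatial effects Z ~ MVN(0, sigma_z^2 K(theta)).

    Unconstrained MVN draws are projected onto the sum-to-zero subspace
    (Z <- Z - mean(Z)), so the empirical covariance converges to
    ``P (sigma_z^2 K) P`` with P the centering projector.

    Returns an (n_draws, n_blocks) array.
    """
    if sigma_z < 0:
        raise ValueError("sigma_z must be >= 0")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    if n == 1 or sigma_z == 0.0:
        return np.zeros((n_draws, n))
    K = exp_correlation(D, theta)
    L = _chol_psd(K, jitter)
    z = sigma_z * (rng.standard_normal((n_draws, n)) @ L.T)
    return z - z.mean(axis=1, keepdims=True)


def conditional_predict(
    z_obs: np.ndarray,
    coords_obs: np.ndarray,
    coords_new: np.ndarray,
    theta,
    sigma_z,
    jitter: float = DEFAULT_JITTER,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-field conditional (kriging) mean and variance at new blocks.

    ``z_obs`` may be a single field (n_obs,) or per-posterior-draw fields
    (n_draws, n_obs); ``theta`` and ``sigma_z`` may be scalars or per-draw
    vectors.  Conditioning uses the unconstrained exponential covariance
    ``sigma_z^2 K``; mean = k*^T K^{-1} z_obs, var = sigma_z^2 (1 - k*^T K^{-1} k*).

    Returns (mean, var), each (n_draws, n_new) (squeezed to (n_new,) for a
    single field).
    """
    z_obs = np.atleast_2d(np.asarray(z_obs, dtype=float))
    single = z_obs.shape[0] == 1 and np.ndim(theta) == 0
    coords_obs = np.asarray(coords_obs, dtype=float)
    coords_new = np.atleast_2d(np.asarray(coords_new, dtype=float))
    if coords_obs.shape[0] == 0:
        raise ValueError("no observed blocks to condition on")
    n_draws = z_obs.shape[0]
    theta_arr = np.broadcast_to(np.asarray(theta, dtype=float).ravel(), (n_draws,)) \
        if np.ndim(theta) > 0 else np.full(n_draws, float(theta))
    sig_arr = np.broadcast_to(np.asarray(sigma_z, dtype=float).ravel(), (n_draws,)) \
        if np.ndim(sigma_z) > 0 else np.full(n_draws, float(sigma_z))

    all_coords = np.vstack([coords_obs, coords_new])
    d_all = distance_matrix(all_coords)
    n_obs = coords_obs.shape[0]
    d_oo = d_all[:n_obs, :n_obs]
    d_on = d_all[:n_obs, n_obs:]

    mean = np.empty((n_draws, coords_new.shape[0]))
    var = np.empty_like(mean)
    # group draws by unique theta so the factorization is reused when
    # theta is a scalar
    order = np.argsort(theta_arr, kind="stable")
    i = 0
    while i < n_draws:
        j = i
        th = theta_arr[order[i]]
        while j < n_draws and theta_arr[order[j]] == th:
            j += 1
        idx = order[i:j]
        K = exp_correlation(d_oo, th)
        kstar = exp_correlation(d_on, th)  # (n_obs, n_new)
        cf = cho_factor(K + jitter * np.eye(n_obs), lower=True)
        alpha = cho_solve(cf, kstar)  # K^{-1} k*
        mean[idx] = z_obs[idx] @ alpha
        resid = np.clip(1.0 - np.sum(kstar * alpha, axis=0), 0.0, None)
        var[idx] = sig_arr[idx, None] ** 2 * resid[None, :]
        i = j
    if single:
        return mean[0], var[0]
    return mean, var
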