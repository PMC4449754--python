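"""Synthetic banding-data generator with the exact structure the models assume.

Count cubes are generated from known parameter values: a sum-to-zero
exponential-correlation spatial field and block-year heterogeneity enter a
logit-linear predictor with age- and band-type-specific intercepts and
age-specific covariate slopes; direct recoveries are binomial thinnings of
the releases and recoveries in Canada are a further binomial split.
Release counts are negative-binomial around an age-specific mean so sparse
northern-style blocks occur.  Every latent quantity is returned alongside
the cube so parameter-recovery tests can compare against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import spatial
from .ingest import AGE_CLASSES, CountCube

__all__ = ["TruthConfig", "simulate_covariates", "simulate_cube", "band_type_shares"]

# default intercepts on the logit scale per band type: (juvenile, adult).
# Recovery values sit near typical black-duck direct-recovery probabilities
# (juveniles ~0.07-0.11, adults lower); Canada-proportion values near
# 0.5-0.67 with juveniles recovered in Canada more often than adults.
DEFAULT_RECOVERY_ALPHA = {
    "avise": (-2.62, -3.03), "zip": (-2.57, -2.94),
    "tollfree": (-2.08, -2.41), "web": (-2.19, -1.77),
}
DEFAULT_CANADA_ALPHA = {
    "avise": (0.70, 0.03), "zip": (-0.10, 0.0),
    "tollfree": (-0.02, 0.0), "web": (0.15, 0.0),
}
COVARIATE_NAMES = ("effort", "regulation", "banding_effort")


def _default_beta():
    # rows: effort, regulation, banding_effort; cols: (juvenile, adult)
    return np.array([[0.2, 0.05], [0.0, -0.4], [-0.13, -0.07]])


def _default_gamma():
    return np.array([[-0.18, 0.0], [0.0, 0.0], [0.10, 0.05]])


@dataclass
class TruthConfig:
    """Known generative parameters for one synthetic study.

    Defaults are sized for desk tests: 50 blocks over an eastern-Canada-like
    window, 20 years, 2 band types with a mid-study rollout, recovery field
    sigma_z = 0.5 with a 500 km effective range, heterogeneity
    sigma_e = 0.3, and a juvenile hunting-effort slope of 0.2.
    """

    n_blocks: int = 50
    lat_range: tuple = (44, 54)
    lon_range: tuple = (-79, -62)
    years: tuple = (1970, 1989)
    band_types: tuple = ("avise", "tollfree")
    rollout: dict | None = None           # band type -> first deployment year
    rollout_ramp: int = 3                 # years to hand over between types
    alpha: np.ndarray | None = None       # (2, B) recovery intercepts
    beta: np.ndarray = dc_field(default_factory=_default_beta)   # (3, 2)
    sigma_z: float = 0.5
    theta: float = -np.log(0.05) / 500.0  # 500 km effective range
    sigma_e: float = 0.3
    canada_alpha: np.ndarray | None = None
    canada_beta: np.ndarray = dc_field(default_factory=_default_gamma)
    canada_sigma_z: float = 1.0
    canada_theta: float = -np.log(0.05) / 1200.0
    canada_sigma_e: float = 0.5
    mean_releases: tuple = (30.0, 8.0)    # per block-year, (juvenile, adult)
    nb_dispersion: float = 1.5            # NB size; var = m + m^2/size
    changepoint: int | None = None        # regulation-era change, default year 14
    seed: int = 20260919

    def __post_init__(self):
        b = len(self.band_types)
        if self.alpha is None:
            self.alpha = np.array(
                [[DEFAULT_RECOVERY_ALPHA[bt][a] for bt in self.band_types]
                 for a in range(2)])
        if self.canada_alpha is None:
            self.canada_alpha = np.array(
                [[DEFAULT_CANADA_ALPHA[bt][a] for bt in self.band_types]
                 for a in range(2)])
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(2, b)
        self.canada_alpha = np.asarray(self.canada_alpha, dtype=float).reshape(2, b)
        self.beta = np.asarray(self.beta, dtype=float).reshape(3, 2)
        self.canada_beta = np.asarray(self.canada_beta, dtype=float).reshape(3, 2)
        if self.rollout is None:
            span = self.years[1] - self.years[0] + 1
            self.rollout = {bt: self.years[0] + (j * span) // len(self.band_types)
                            for j, bt in enumerate(self.band_types)}
        if self.changepoint is None:
            self.changepoint = self.years[0] + 13
        for name in ("sigma_z", "sigma_e", "canada_sigma_z", "canada_sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.theta <= 0 or self.canada_theta <= 0:
            raise ValueError("theta must be > 0")

    @property
    def year_list(self) -> list:
        return list(range(self.years[0], self.years[1] + 1))


def simulate_covariates(years, seed=None, changepoint: int | None = None,
                        effort_start: float = 600_000.0, effort_end: float = 250_000.0,
                        effort_noise_sd: float = 20_000.0,
                        banding_mean: float = 2372.0, banding_noise_sd: float = 400.0) -> pd.DataFrame:
    """Annual covariate series: hunting effort, regulation era, banding effort.

    Hunting effort (a permit/duck-stamp sales analogue) declines linearly
    from ``effort_start`` to ``effort_end`` with Gaussian noise; the
    regulation indicator flips from 0 to 1 at ``changepoint``; banding
    effort is stationary noise around ``banding_mean``.  Each series is
    returned raw and z-scored (suffix ``_z``).
    """
    years = list(years)
    if changepoint is None:
        changepoint = years[0] + 13
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, len(years))
    effort = effort_start + (effort_end - effort_start) * t
    effort = effort + rng.normal(0.0, effort_noise_sd, len(years))
    regulation = (np.asarray(years) >= changepoint).astype(float)
    banding = banding_mean + rng.normal(0.0, banding_noise_sd, len(years))
    banding = np.clip(banding, 1.0, None)
    df = pd.DataFrame({"year": years, "effort": effort,
                       "regulation": regulation, "banding_effort": banding})
    for col in COVARIATE_NAMES:
        sd = df[col].std(ddof=0)
        df[col + "_z"] = 0.0 if sd == 0 else (df[col] - df[col].mean()) / sd
    return df


def band_type_shares(years, band_types, rollout: dict, ramp: int = 3) -> np.ndarray:
    """Per-year mixing proportions of band types under a rollout schedule.

    Each newly deployed type takes over linearly across ``ramp`` years; the
    remaining share keeps the previous mixture.  Rows sum to one.
    """
    years = list(years)
    shares = np.zeros((len(years), len(band_types)))
    for tix, yr in enumerate(years):
        w = np.zeros(len(band_types))
        w[0] = 1.0
        for j, bt in enumerate(band_types[1:], start=1):
            frac = np.clip((yr - rollout[bt] + 1) / ramp, 0.0, 1.0)
            w[:j] *= 1.0 - frac
            w[j] = frac
        shares[tix] = w / w.sum()
    return shares


def _draw_releases(rng, truth: TruthConfig, shares: np.ndarray) -> np.ndarray:
    """Negative-binomial releases per (block, year, age), split over band types."""
    nb, nt = truth.n_blocks, len(truth.year_list)
    n_ages, n_bt = 2, len(truth.band_types)
    N = np.zeros((nb, nt, n_ages, n_bt), dtype=np.int64)
    k = truth.nb_dispersion
    for a in range(n_ages):
        m = truth.mean_releases[a]
        p = k / (k + m)
        totals = rng.negative_binomial(k, p, size=(nb, nt))
        for t in range(nt):
            nz = totals[:, t] > 0
            if nz.any():
                N[nz, t, a, :] = rng.multinomial(totals[nz, t], shares[t])
    return N


def _select_blocks(rng, truth: TruthConfig) -> list:
    lats = np.arange(truth.lat_range[0], truth.lat_range[1])
    lons = np.arange(truth.lon_range[0], truth.lon_range[1])
    cand = [(int(la), int(lo)) for la in lats for lo in lons]
    if truth.n_blocks > len(cand):
        raise ValueError(f"n_blocks={truth.n_blocks} exceeds the {len(cand)}-block grid")
    idx = rng.choice(len(cand), size=truth.n_blocks, replace=False)
    return sorted(cand[i] for i in idx)


def simulate_cube(truth: TruthConfig, covariates: pd.DataFrame | None = None,
                  seed=None):
    """Generate a CountCube plus the full latent truth record.

    Returns ``(cube, truth_record)`` where the record holds the spatial
    fields, heterogeneity draws, cellwise probabilities f and P_CAN, the
    covariate table, and the generating parameters -- everything a
    parameter-recovery test needs.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    blocks = _select_blocks(rng, truth)
    years = truth.year_list
    if covariates is None:
        covariates = simulate_covariates(
            years, seed=rng.integers(2 ** 31), changepoint=truth.changepoint)
    X = covariates.set_index("year").loc[years, [c + "_z" for c in COVARIATE_NAMES]] \
        .to_numpy(dtype=float)

    centroids = np.array([(b[0] + 0.5, b[1] + 0.5) for b in blocks])
    D = spatial.distance_matrix(centroids)
    nb, nt, n_bt = len(blocks), len(years), len(truth.band_types)

    shares = band_type_shares(years, truth.band_types, truth.rollout, truth.rollout_ramp)
    N = _draw_releases(rng, truth, shares)

    def _latents(sigma_z, theta, sigma_e):
        z = spatial.sample_constrained_field(D, theta, sigma_z, 1, seed=rng)[0]
        eps = rng.normal(0.0, sigma_e, size=(nb, nt)) if sigma_e > 0 else np.zeros((nb, nt))
        return z, eps

    def _probs(alpha, beta, z, eps):
        xb = X @ beta  # (nt, 2)
        # index order is (block, year, age, band type)
        mu = np.empty((nb, nt, 2, n_bt))
        for a in range(2):
            for b in range(n_bt):
                mu[:, :, a, b] = alpha[a, b] + xb[:, a][None, :] + z[:, None] + eps
        return expit(mu)

    z_f, eps_f = _latents(truth.sigma_z, truth.theta, truth.sigma_e)
    f = _probs(truth.alpha, truth.beta, z_f, eps_f)
    y = rng.binomial(N, f)

    z_c, eps_c = _latents(truth.canada_sigma_z, truth.canada_theta, truth.canada_sigma_e)
    p_can = _probs(truth.canada_alpha, truth.canada_beta, z_c, eps_c)
    x = rng.binomial(y, p_can)

    cube = CountCube(N=N, y=y, x=x, blocks=blocks, years=years,
                     ages=AGE_CLASSES, band_types=truth.band_types)
    record = {
        "config": truth, "blocks": blocks, "centroids": centroids, "D": D,
        "covariates": covariates, "X": X, "band_shares": shares,
        "alpha": truth.alpha, "beta": truth.beta,
        "z": z_f, "eps": eps_f, "f": f,
        "canada_alpha": truth.canada_alpha, "canada_beta": truth.canada_beta,
        "z_can": z_c, "eps_can": eps_c, "p_can": p_can,
        "sigma_z": truth.sigma_z, "theta": truth.theta, "sigma_e": truth.sigma_e,
        "canada_sigma_z": truth.canada_sigma_z, "canada_theta": truth.canada_theta,
        "canada_sigma_e": truth.canada_sigma_e,
    }
    return cube, record
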