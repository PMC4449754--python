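"""Spatially correlated binomial-logit hierarchical model.

One generic model serves two roles: the *recovery* submodel (trials = band
releases N, successes = direct recoveries y) and the *canada* submodel
(trials = direct recoveries y, successes = recoveries in Canada x).  On the
logit scale each cell's probability is

    mu[i,t,a,b] = alpha[a,b] + sum_k beta[k,a] * X[t,k] + Z[i] + eps[i,t]

with age- and band-type-specific intercepts alpha (four (juvenile, adult)
pairs drawn from one bivariate normal with half-Cauchy(0,5) scales and a
uniform correlation), age-specific covariate slopes beta ~ Normal(0,5)
truncated to (-20, 20), a sum-to-zero spatial field Z with exponential
correlation (sigma_Z, theta), and block-year heterogeneity
eps ~ Normal(0, sigma_e).  sigma_Z and sigma_e get half-Cauchy(0,1) priors
truncated to (0, 20); theta gets a uniform prior whose bounds come from the
extremes of the distance matrix.

The posterior is sampled with the package's NUTS implementation on an
unconstrained parameterization: the field is expressed in an orthonormal
sum-to-zero basis (hard constraint), scales use bounded-sigmoid transforms,
and intercepts are non-centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln

from . import spatial
from .ingest import CountCube
from .sampler import nuts, split_rhat

__all__ = [
    "PriorConfig", "ModelSpec", "PosteriorDraws", "build_spec",
    "log_likelihood", "fit", "predict_probability", "split_rhat",
]

DEFAULT_COVARIATES = ("effort", "regulation", "banding_effort")


@dataclass
class PriorConfig:
    """Hyperparameters of the fixed priors."""

    intercept_scale: float = 5.0   # half-Cauchy scale of the intercept SDs
    slope_sd: float = 5.0          # Normal SD of covariate slopes
    slope_bound: float = 20.0      # truncation of slopes to (-bound, bound)
    sd_scale: float = 1.0          # half-Cauchy scale for sigma_e, sigma_Z
    sd_bound: float = 20.0         # truncation of sigma_e, sigma_Z to (0, bound)
    jitter: float = 1e-9


@dataclass
class ModelSpec:
    """Design of one binomial-logit submodel, ready to fit."""

    role: str
    trials: np.ndarray            # flat, active cells only (trials > 0)
    successes: np.ndarray
    ib: np.ndarray                # block index per active cell
    it: np.ndarray                # year index
    ia: np.ndarray                # age index
    ig: np.ndarray                # band-type index
    iby: np.ndarray               # active block-year index
    by_pairs: np.ndarray          # (n_by, 2) block, year of each active block-year
    X: np.ndarray                 # (n_years, K) z-scored covariates
    covariate_names: tuple
    cov_means: np.ndarray
    cov_sds: np.ndarray
    blocks: list
    years: list
    ages: tuple
    band_types: tuple
    D: np.ndarray
    centroids: np.ndarray
    theta_bounds: tuple
    priors: PriorConfig = field(default_factory=PriorConfig)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_by(self) -> int:
        return self.by_pairs.shape[0]

    @property
    def n_cov(self) -> int:
        return self.X.shape[1]

    @property
    def n_bt(self) -> int:
        return len(self.band_types)


def build_spec(cube: CountCube, covariates: pd.DataFrame, role: str,
               priors: PriorConfig | None = None,
               covariate_cols: tuple = DEFAULT_COVARIATES,
               allow_empty: bool = False) -> ModelSpec:
    """Assemble a ModelSpec from a count cube and annual covariates.

    ``role`` is ``"recovery"`` (trials N, successes y) or ``"canada"``
    (trials y, successes x).  Cells with zero trials are kept in the cube
    index but excluded from the likelihood; covariates are z-scored with
    the means/SDs stored for back-transformation.
    """
    if role == "recovery":
        trials, successes = cube.N, cube.y
    elif role == "canada":
        trials, successes = cube.y, cube.x
    else:
        raise ValueError(f"role must be 'recovery' or 'canada', got {role!r}")

    cov = covariates.set_index("year").loc[list(cube.years), list(covariate_cols)]
    raw = cov.to_numpy(dtype=float)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [c for c, s in zip(covariate_cols, sds) if s == 0]
        raise ValueError(f"covariate(s) with zero variance over the fitted years: {bad}")
    X = (raw - means) / sds

    active = trials > 0
    if not active.any() and not allow_empty:
        raise ValueError("nothing to fit: all cells have zero trials")
    ib, it, ia, ig = np.nonzero(active)
    # active block-years (epsilon is shared across age/band type in a block-year)
    by_key = ib * len(cube.years) + it
    uniq, iby = np.unique(by_key, return_inverse=True)
    by_pairs = np.column_stack([uniq // len(cube.years), uniq % len(cube.years)])

    centroids = cube.centroids
    D = spatial.distance_matrix(centroids)
    if len(cube.blocks) > 1:
        off = D[np.triu_indices_from(D, k=1)]
        theta_bounds = spatial.theta_prior_bounds(off.max(), off.min())
    else:
        theta_bounds = (1e-6, 1.0)

    return ModelSpec(
        role=role,
        trials=trials[active].astype(float),
        successes=successes[active].astype(float),
        ib=ib, it=it, ia=ia, ig=ig, iby=iby, by_pairs=by_pairs,
        X=X, covariate_names=tuple(covariate_cols),
        cov_means=means, cov_sds=sds,
        blocks=list(cube.blocks), years=list(cube.years),
        ages=tuple(cube.ages), band_types=tuple(cube.band_types),
        D=D, centroids=centroids, theta_bounds=theta_bounds,
        priors=priors or PriorConfig(),
    )


def _linear_predictor(params: dict, spec: ModelSpec) -> np.ndarray:
    alpha = np.asarray(params["alpha"], dtype=float)       # (2, n_bt)
    beta = np.asarray(params["beta"], dtype=float)         # (K, 2)
    z = np.asarray(params.get("z", np.zeros(spec.n_blocks)), dtype=float)
    eps = params.get("eps", 0.0)
    eps = np.asarray(eps, dtype=float) if np.ndim(eps) else np.full(spec.n_by, float(eps))
    xb = spec.X @ beta                                     # (T, 2)
    return alpha[spec.ia, spec.ig] + xb[spec.it, spec.ia] + z[spec.ib] + eps[spec.iby]


def log_likelihood(params: dict, spec: ModelSpec) -> float:
    """Binomial log likelihood over active cells (zero-trial cells add 0).

    ``params`` holds ``alpha`` (n_ages, n_bt), ``beta`` (K, n_ages), and
    optionally ``z`` (n_blocks) and ``eps`` (n active block-years).
    Includes the binomial coefficients.
    """
    for key in ("alpha", "beta"):
        if not np.all(np.isfinite(params[key])):
            raise ValueError(f"non-finite values in params[{key!r}]")
    if spec.trials.size == 0:
        return 0.0
    mu = _linear_predictor(params, spec)
    n, y = spec.trials, spec.successes
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    # y*mu - n*log(1 + exp(mu)), with a stable softplus
    softplus = np.logaddexp(0.0, mu)
    return float(np.sum(const + y * mu - n * softplus))


# ---------------------------------------------------------------------------
# unconstrained log posterior with analytic gradient

class _LogPosterior:
    """Packs the model into f(zvec) -> (log density, gradient).

    Parameterization: intercepts and the spatial field are *centered*
    (sampled on their natural scale, with the hierarchical density as a
    prior term) because the data inform them strongly; the block-year
    heterogeneity is non-centered (eps = sigma_e * e_raw) because single
    block-years are weakly informed.  Scales and the decay rate use
    bounded-sigmoid transforms with their log-Jacobians; the field lives
    in an orthonormal sum-to-zero basis (hard constraint).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        p = spec.priors
        self.n_bt = spec.n_bt
        self.K = spec.n_cov
        self.nb = spec.n_blocks
        self.nby = spec.n_by
        self.A = spatial.sum_to_zero_basis(self.nb)        # (nb, nb-1)
        self.nv = self.A.shape[1]
        self.th_lo, self.th_hi = spec.theta_bounds
        # slices of the unconstrained vector
        sizes = [2 * self.n_bt, 2, 1, self.K * 2, self.nv, self.nby, 1, 1, 1]
        names = ["alpha", "u_tau", "w_rho", "u_beta", "w", "e_raw",
                 "u_sigma_z", "u_sigma_e", "u_theta"]
        ofs = np.cumsum([0] + sizes)
        self.slices = {nm: slice(int(a), int(b)) for nm, a, b in zip(names, ofs[:-1], ofs[1:])}
        self.dim = int(ofs[-1])
        self.jitter = p.jitter
        # combined scatter indices for fast bincount reductions
        self._iag = spec.ia * self.n_bt + spec.ig
        self._ita = spec.it * 2 + spec.ia
        self._D = spec.D

    # -- transforms ---------------------------------------------------------
    @staticmethod
    def _bounded(u, lo, hi):
        s = expit(u)
        return lo + (hi - lo) * s, s

    def constrain(self, zvec: np.ndarray) -> dict:
        """Map an unconstrained vector to the named constrained parameters."""
        sp, sl = self.spec, self.slices
        alpha = zvec[sl["alpha"]].reshape(2, self.n_bt)
        tau = np.exp(zvec[sl["u_tau"]])
        rho = np.tanh(zvec[sl["w_rho"]][0])
        beta, _ = self._bounded(zvec[sl["u_beta"]].reshape(self.K, 2),
                                -sp.priors.slope_bound, sp.priors.slope_bound)
        w = zvec[sl["w"]]
        e_raw = zvec[sl["e_raw"]]
        sigma_z, _ = self._bounded(zvec[sl["u_sigma_z"]][0], 0.0, sp.priors.sd_bound)
        sigma_e, _ = self._bounded(zvec[sl["u_sigma_e"]][0], 0.0, sp.priors.sd_bound)
        theta, _ = self._bounded(zvec[sl["u_theta"]][0], self.th_lo, self.th_hi)
        return {
            "alpha": alpha, "beta": beta, "tau": tau, "rho": rho,
            "z": self.A @ w, "eps": sigma_e * e_raw,
            "sigma_z": sigma_z, "sigma_e": sigma_e, "theta": theta,
        }

    # -- density ------------------------------------------------------------
    def __call__(self, zvec: np.ndarray):
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            logp, grad = self._logp_grad(zvec)
        if not np.isfinite(logp):
            return -np.inf, np.zeros_like(zvec)
        return logp, grad

    def _logp_grad(self, zvec: np.ndarray):
        sp, sl, p = self.spec, self.slices, self.spec.priors
        alpha = zvec[sl["alpha"]].reshape(2, self.n_bt)
        u_tau = zvec[sl["u_tau"]]
        tau = np.exp(u_tau)
        w_rho = zvec[sl["w_rho"]][0]
        rho = np.tanh(w_rho)
        u_beta = zvec[sl["u_beta"]]
        s_beta = expit(u_beta)
        beta = (-p.slope_bound + 2 * p.slope_bound * s_beta).reshape(self.K, 2)
        w = zvec[sl["w"]]
        e_raw = zvec[sl["e_raw"]]
        u_sz = zvec[sl["u_sigma_z"]][0]
        s_sz = expit(u_sz)
        sigma_z = p.sd_bound * s_sz
        u_se = zvec[sl["u_sigma_e"]][0]
        s_se = expit(u_se)
        sigma_e = p.sd_bound * s_se
        u_th = zvec[sl["u_theta"]][0]
        s_th = expit(u_th)
        theta = self.th_lo + (self.th_hi - self.th_lo) * s_th

        grad = np.zeros_like(zvec)

        # ---- likelihood
        z_field = self.A @ w
        eps = sigma_e * e_raw
        xb = sp.X @ beta
        mu = alpha[sp.ia, sp.ig] + xb[sp.it, sp.ia] + z_field[sp.ib] + eps[sp.iby]
        n, y = sp.trials, sp.successes
        logp = float(np.sum(y * mu - n * np.logaddexp(0.0, mu)))
        g = y - n * expit(mu)  # d loglik / d mu

        # scatter the cell gradient to each additive term
        g_alpha = np.bincount(self._iag, weights=g, minlength=2 * self.n_bt) \
            .reshape(2, self.n_bt)
        g_xb = np.bincount(self._ita, weights=g, minlength=2 * sp.X.shape[0]) \
            .reshape(sp.X.shape[0], 2)
        g_beta = sp.X.T @ g_xb                              # (K, 2)
        g_zfield = np.bincount(sp.ib, weights=g, minlength=self.nb)
        g_eps = np.bincount(sp.iby, weights=g, minlength=self.nby)

        # ---- intercept pairs: alpha_b ~ MVN(0, Sigma(tau, rho)), centered
        c2 = max(1.0 - rho ** 2, 1e-300)
        det = tau[0] ** 2 * tau[1] ** 2 * c2
        Q = np.array([[tau[1] ** 2, -tau[0] * tau[1] * rho],
                      [-tau[0] * tau[1] * rho, tau[0] ** 2]]) / det
        S = alpha @ alpha.T                                 # 2x2 scatter
        B = self.n_bt
        logp += -0.5 * float(np.sum(Q * S)) \
            - B * (np.log(tau[0]) + np.log(tau[1])) - 0.5 * B * np.log(c2)
        grad[sl["alpha"]] = (g_alpha - Q @ alpha).ravel()
        # tau: half-Cauchy(0, intercept_scale) prior, log transform
        sc = p.intercept_scale
        QS = Q @ S
        for j in range(2):
            dSig = np.zeros((2, 2))
            dSig[j, j] = 2 * tau[j]
            dSig[j, 1 - j] = dSig[1 - j, j] = tau[1 - j] * rho
            dlogp_dtau = 0.5 * float(np.sum((Q @ dSig) * QS.T)) - 0.5 * B * float(np.sum(Q * dSig))
            dlogp_dtau += -2 * tau[j] / (sc ** 2 + tau[j] ** 2)
            grad[sl["u_tau"].start + j] = tau[j] * dlogp_dtau + 1.0  # + log-Jacobian term
        logp += float(np.sum(-np.log1p((tau / sc) ** 2)) + np.sum(u_tau))
        # rho: uniform prior, tanh transform
        dSig = np.array([[0.0, tau[0] * tau[1]], [tau[0] * tau[1], 0.0]])
        dlogp_drho = 0.5 * float(np.sum((Q @ dSig) * QS.T)) - 0.5 * B * float(np.sum(Q * dSig))
        grad[sl["w_rho"]] = (1.0 - rho ** 2) * dlogp_drho - 2.0 * rho
        logp += np.log1p(-rho ** 2)  # Jacobian of tanh

        # ---- slopes: truncated Normal(0, slope_sd) via bounded sigmoid
        logp += float(np.sum(-beta ** 2 / (2 * p.slope_sd ** 2)))
        logp += float(np.sum(np.log(2 * p.slope_bound) + np.log(s_beta) + np.log1p(-s_beta)))
        dbeta_du = 2 * p.slope_bound * s_beta * (1 - s_beta)
        grad[sl["u_beta"]] = ((g_beta - beta / p.slope_sd ** 2).ravel() * dbeta_du
                              + (1.0 - 2.0 * s_beta))

        # ---- spatial field: w ~ MVN(0, sigma_z^2 A' K(theta) A), centered
        K = np.exp(-theta * self._D)
        M = self.A.T @ K @ self.A + self.jitter * np.eye(self.nv)
        cf = cho_factor(M, lower=True)
        Minv_w = cho_solve(cf, w)
        quad = float(w @ Minv_w)
        logp += (-0.5 * quad / sigma_z ** 2 - self.nv * np.log(sigma_z)
                 - float(np.sum(np.log(np.diag(cf[0])))))
        grad[sl["w"]] = self.A.T @ g_zfield - Minv_w / sigma_z ** 2
        # theta enters through the field prior only
        dK = -self._D * K
        dM = self.A.T @ dK @ self.A
        Minv = cho_solve(cf, np.eye(self.nv))
        dlogp_dth = 0.5 * float(Minv_w @ dM @ Minv_w) / sigma_z ** 2 \
            - 0.5 * float(np.sum(Minv * dM.T))
        dth_du = (self.th_hi - self.th_lo) * s_th * (1 - s_th)
        grad[sl["u_theta"]] = dlogp_dth * dth_du + (1.0 - 2.0 * s_th)
        logp += np.log(self.th_hi - self.th_lo) + np.log(s_th) + np.log1p(-s_th)

        # ---- heterogeneity: e_raw ~ N(0,1), eps = sigma_e * e_raw
        grad[sl["e_raw"]] = sigma_e * g_eps - e_raw
        logp += -0.5 * float(e_raw @ e_raw)

        # ---- scales: half-Cauchy(0, sd_scale) truncated (0, sd_bound)
        g_sz_lik = quad / sigma_z ** 3 - self.nv / sigma_z   # from the field prior
        g_se_lik = float(g_eps @ e_raw)                      # from the likelihood
        for u_s, s_s, sigma, g_lik, key in (
            (u_sz, s_sz, sigma_z, g_sz_lik, "u_sigma_z"),
            (u_se, s_se, sigma_e, g_se_lik, "u_sigma_e"),
        ):
            logp += -np.log1p((sigma / p.sd_scale) ** 2)
            logp += np.log(p.sd_bound) + np.log(s_s) + np.log1p(-s_s)
            dsig_du = p.sd_bound * s_s * (1 - s_s)
            dprior = -2 * sigma / (p.sd_scale ** 2 + sigma ** 2)
            grad[self.slices[key]] = (g_lik + dprior) * dsig_du + (1.0 - 2.0 * s_s)

        return logp, grad


@dataclass
class PosteriorDraws:
    """Per-chain posterior draws of the constrained parameters.

    ``params`` maps name -> array of shape (n_chains, n_draws, ...); the
    field ``z`` sums to zero over blocks in every draw by construction.
    """

    params: dict
    spec: ModelSpec
    seed: int
    n_warmup: int
    divergences: np.ndarray
    step_sizes: np.ndarray
    accept_stat: np.ndarray

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled across chains: (n_chains * n_draws, ...)."""
        a = self.params[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def rhat(self) -> dict:
        """Split R-hat per scalar component of every parameter."""
        out = {}
        for name, a in self.params.items():
            flat = a.reshape(a.shape[0], a.shape[1], -1)
            for j in range(flat.shape[2]):
                label = name if flat.shape[2] == 1 else f"{name}[{j}]"
                out[label] = split_rhat(flat[:, :, j])
        return out

    def summary(self) -> pd.DataFrame:
        from .report import summary_table

        return summary_table(self)


def _scalar_names(spec: ModelSpec):
    names = {}
    for a, age in enumerate(spec.ages):
        for b, bt in enumerate(spec.band_types):
            names[f"alpha[{age},{bt}]"] = ("alpha", (a, b))
    for k, cn in enumerate(spec.covariate_names):
        for a, age in enumerate(spec.ages):
            names[f"beta[{cn},{age}]"] = ("beta", (k, a))
    return names


def fit(spec: ModelSpec, n_chains: int = 6, n_warmup: int = 250, n_iter: int = 1250,
        seed: int = 0, target_accept: float = 0.8, max_treedepth: int = 8,
        init_scale: float = 0.5) -> PosteriorDraws:
    """Sample the posterior with NUTS; returns post-warmup constrained draws.

    Defaults mirror a 6-chain run with a 250-iteration burn-in; ``n_iter``
    counts post-warmup draws per chain.  A divergent-transition fraction
    above 10% triggers a prominent warning (the draws are still returned).
    """
    lp = _LogPosterior(spec)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    keep = {"alpha": (2, spec.n_bt), "beta": (spec.n_cov, 2), "tau": (2,),
            "rho": (), "sigma_z": (), "sigma_e": (), "theta": (),
            "z": (spec.n_blocks,), "eps": (spec.n_by,)}
    params = {k: np.empty((n_chains, n_iter) + shp) for k, shp in keep.items()}
    divergences = np.zeros(n_chains, dtype=int)
    step_sizes = np.zeros(n_chains)
    accept = np.zeros((n_chains, n_iter))
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        z0 = init_scale * rng.uniform(-1.0, 1.0, lp.dim)
        res = nuts(lp, z0, n_warmup, n_iter, rng,
                   target_accept=target_accept, max_treedepth=max_treedepth)
        divergences[c] = res["divergences"]
        step_sizes[c] = res["step_size"]
        accept[c] = res["accept_stat"]
        for i, zvec in enumerate(res["samples"]):
            con = lp.constrain(zvec)
            for k in keep:
                params[k][c, i] = con[k]
    frac_div = divergences.sum() / (n_chains * n_iter)
    if frac_div > 0.10:
        import warnings

        warnings.warn(
            f"{100 * frac_div:.1f}% divergent transitions; posterior geometry is "
            "poorly explored -- treat these draws with caution", stacklevel=2)
    return PosteriorDraws(params=params, spec=spec, seed=seed, n_warmup=n_warmup,
                          divergences=divergences, step_sizes=step_sizes,
                          accept_stat=accept)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist posterior draws and sampler metadata to a compressed npz."""
    np.savez_compressed(
        path, **{f"param_{k}": v for k, v in draws.params.items()},
        seed=draws.seed, n_warmup=draws.n_warmup, divergences=draws.divergences,
        step_sizes=draws.step_sizes, accept_stat=draws.accept_stat)


def load_draws(path, spec: ModelSpec) -> PosteriorDraws:
    """Rebuild PosteriorDraws saved by :func:`save_draws` for ``spec``."""
    with np.load(path) as data:
        params = {k[6:]: data[k] for k in data.files if k.startswith("param_")}
        return PosteriorDraws(
            params=params, spec=spec, seed=int(data["seed"]),
            n_warmup=int(data["n_warmup"]), divergences=data["divergences"],
            step_sizes=data["step_sizes"], accept_stat=data["accept_stat"])


def predict_probability(draws: PosteriorDraws, spec: ModelSpec, year, age, band_type,
                        blocks=None, new_coords=None,
                        heterogeneity: str = "zero",
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-draw probability (f or P_CAN) at the requested blocks.

    ``blocks`` selects fitted blocks (indices into ``spec.blocks``; default
    all); ``new_coords`` instead predicts at unfitted (lat, lon) centroids
    via Gaussian-field conditioning on each draw's Z (sampling the
    conditional distribution when ``rng`` is given, otherwise using the
    conditional mean).  ``heterogeneity`` is ``"zero"`` for population-level
    prediction or ``"integrate"`` to draw eps ~ N(0, sigma_e) (requires
    ``rng``).  Returns (n_total_draws, n_requested) probabilities.
    """
    if age not in spec.ages:
        raise ValueError(f"unknown age {age!r}; expected one of {spec.ages}")
    if band_type not in spec.band_types:
        raise ValueError(f"unknown band type {band_type!r}; expected one of {spec.band_types}")
    if year not in spec.years:
        raise ValueError(f"year {year} not in the fitted span")
    a = spec.ages.index(age)
    b = spec.band_types.index(band_type)
    t = spec.years.index(year)

    alpha = draws.stacked("alpha")[:, a, b]
    beta = draws.stacked("beta")[:, :, a]
    lin = alpha + beta @ spec.X[t]

    if new_coords is not None:
        z_obs = draws.stacked("z")
        mean, var = spatial.conditional_predict(
            z_obs, spec.centroids, np.atleast_2d(new_coords),
            draws.stacked("theta"), draws.stacked("sigma_z"))
        z_at = mean + (np.sqrt(var) * rng.standard_normal(var.shape) if rng is not None else 0.0)
    else:
        idx = np.arange(spec.n_blocks) if blocks is None else np.asarray(blocks)
        z_at = draws.stacked("z")[:, idx]
    lin = lin[:, None] + z_at

    if heterogeneity == "integrate":
        if rng is None:
            raise ValueError("heterogeneity='integrate' requires an rng")
        lin = lin + draws.stacked("sigma_e")[:, None] * rng.standard_normal(lin.shape)
    elif heterogeneity != "zero":
        raise ValueError("heterogeneity must be 'zero' or 'integrate'")
    return expit(lin)
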