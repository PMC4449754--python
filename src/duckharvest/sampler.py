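"""No-U-Turn Hamiltonian Monte Carlo on an unconstrained parameter vector.

A self-contained NUTS implementation: tree doubling with the slice
acceptance rule, dual-averaging step-size adaptation toward a target
acceptance statistic, and windowed estimation of a diagonal mass matrix
during warmup.  The target is supplied as a callable returning the log
density and its gradient; all constraint handling (bounded or positive
parameters) is the caller's responsibility via transformations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["nuts", "split_rhat"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    mu: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    count: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_prob: float, target: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (target - accept_prob)
        log_eps = self.mu - math.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return math.exp(log_eps)


def _leapfrog(logp_grad, z, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    z = z + eps * inv_mass * p
    logp, grad = logp_grad(z)
    p = p + 0.5 * eps * grad
    return z, p, logp, grad


def _find_reasonable_step(logp_grad, z, logp, grad, inv_mass, rng) -> float:
    eps = 1.0
    p = rng.standard_normal(z.shape) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * np.sum(inv_mass * p * p)
    z1, p1, logp1, _ = _leapfrog(logp_grad, z, p, grad, eps, inv_mass)
    h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        z1, p1, logp1, _ = _leapfrog(logp_grad, z, p, grad, eps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * math.log(0.5):
            break
    return max(eps, 1e-10)


class _Tree:
    __slots__ = ("z_minus", "p_minus", "grad_minus", "z_plus", "p_plus", "grad_plus",
                 "z_prop", "logp_prop", "grad_prop", "n_valid", "keep_going",
                 "sum_accept", "n_steps", "diverged")


def _build_tree(logp_grad, z, p, grad, log_u, direction, depth, eps, inv_mass, h0, rng):
    t = _Tree()
    if depth == 0:
        z1, p1, logp1, grad1 = _leapfrog(logp_grad, z, p, grad, direction * eps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        t.z_minus = t.z_plus = t.z_prop = z1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        t.n_valid = 1 if log_u <= h1 else 0
        t.diverged = log_u - _MAX_DELTA_H > h1
        t.keep_going = not t.diverged
        t.sum_accept = min(1.0, math.exp(min(h1 - h0, 0.0)))
        t.n_steps = 1
        return t
    # recursion: build left and right subtrees
    t = _build_tree(logp_grad, z, p, grad, log_u, direction, depth - 1, eps, inv_mass, h0, rng)
    if t.keep_going:
        if direction == -1:
            t2 = _build_tree(logp_grad, t.z_minus, t.p_minus, t.grad_minus, log_u,
                             direction, depth - 1, eps, inv_mass, h0, rng)
            t.z_minus, t.p_minus, t.grad_minus = t2.z_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(logp_grad, t.z_plus, t.p_plus, t.grad_plus, log_u,
                             direction, depth - 1, eps, inv_mass, h0, rng)
            t.z_plus, t.p_plus, t.grad_plus = t2.z_plus, t2.p_plus, t2.grad_plus
        if t2.n_valid > 0 and rng.random() < t2.n_valid / max(t.n_valid + t2.n_valid, 1):
            t.z_prop, t.logp_prop, t.grad_prop = t2.z_prop, t2.logp_prop, t2.grad_prop
        t.n_valid += t2.n_valid
        t.sum_accept += t2.sum_accept
        t.n_steps += t2.n_steps
        t.diverged = t.diverged or t2.diverged
        t.keep_going = (t2.keep_going and not t.diverged
                        and _no_u_turn(t.z_minus, t.z_plus, t.p_minus, t.p_plus, inv_mass))
    return t


def _no_u_turn(z_minus, z_plus, p_minus, p_plus, inv_mass) -> bool:
    dz = z_plus - z_minus
    return (np.dot(dz, inv_mass * p_minus) >= 0) and (np.dot(dz, inv_mass * p_plus) >= 0)


def _adaptation_windows(n_warmup: int):
    """(start, end) slow windows for mass estimation, Stan-style schedule."""
    if n_warmup < 40:
        return []
    init_buf = max(15, int(0.15 * n_warmup))
    term_buf = max(10, int(0.10 * n_warmup))
    windows = []
    pos = init_buf
    size = max(15, int(0.10 * n_warmup))
    while pos + size < n_warmup - term_buf:
        nxt = pos + size
        # absorb a too-small final window
        if nxt + 2 * size >= n_warmup - term_buf:
            nxt = n_warmup - term_buf
        windows.append((pos, nxt))
        pos = nxt
        size *= 2
    return windows


def nuts(
    logp_grad,
    z0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 8,
):
    """Run one NUTS chain; returns dict with post-warmup draws and stats.

    ``logp_grad(z) -> (float, ndarray)`` must be finite at ``z0``.
    """
    z = np.asarray(z0, dtype=float).copy()
    logp, grad = logp_grad(z)
    if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
        raise ValueError("non-finite log density or gradient at the initial point")
    dim = z.size
    inv_mass = np.ones(dim)

    eps = _find_reasonable_step(logp_grad, z, logp, grad, inv_mass, rng)
    da = _DualAveraging(mu=math.log(10.0 * eps))
    windows = _adaptation_windows(n_warmup)
    w_idx = 0
    acc = np.zeros(dim)
    acc2 = np.zeros(dim)
    acc_n = 0

    samples = np.empty((n_samples, dim))
    accept_stats = np.empty(n_samples)
    tree_depths = np.zeros(n_samples, dtype=int)
    divergences = 0

    total = n_warmup + n_samples
    for it in range(total):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(inv_mass * p * p)
        log_u = h0 + math.log(max(rng.random(), 1e-300))
        z_minus = z_plus = z
        p_minus = p_plus = p
        grad_minus = grad_plus = grad
        z_prop, logp_prop, grad_prop = z, logp, grad
        n_valid = 1
        depth = 0
        sum_accept, n_steps = 0.0, 0
        diverged = False
        while depth < max_treedepth:
            direction = -1 if rng.random() < 0.5 else 1
            if direction == -1:
                t = _build_tree(logp_grad, z_minus, p_minus, grad_minus, log_u,
                                direction, depth, eps, inv_mass, h0, rng)
                z_minus, p_minus, grad_minus = t.z_minus, t.p_minus, t.grad_minus
            else:
                t = _build_tree(logp_grad, z_plus, p_plus, grad_plus, log_u,
                                direction, depth, eps, inv_mass, h0, rng)
                z_plus, p_plus, grad_plus = t.z_plus, t.p_plus, t.grad_plus
            sum_accept += t.sum_accept
            n_steps += t.n_steps
            if t.diverged:
                diverged = True
            if t.keep_going and t.n_valid > 0 and rng.random() < t.n_valid / n_valid:
                z_prop, logp_prop, grad_prop = t.z_prop, t.logp_prop, t.grad_prop
            n_valid += t.n_valid
            depth += 1
            if not (t.keep_going and _no_u_turn(z_minus, z_plus, p_minus, p_plus, inv_mass)):
                break
        z, logp, grad = z_prop, logp_prop, grad_prop
        accept_prob = sum_accept / max(n_steps, 1)

        if it < n_warmup:
            eps = da.update(accept_prob, target_accept)
            if w_idx < len(windows):
                lo, hi = windows[w_idx]
                if lo <= it < hi:
                    acc += z
                    acc2 += z * z
                    acc_n += 1
                if it == hi - 1:
                    var = acc2 / acc_n - (acc / acc_n) ** 2
                    # regularize toward unit variance as Stan does
                    var = (acc_n / (acc_n + 5.0)) * var + (5.0 / (acc_n + 5.0)) * 1e-3
                    inv_mass = np.clip(var, 1e-10, None)
                    acc[:] = 0.0
                    acc2[:] = 0.0
                    acc_n = 0
                    w_idx += 1
                    eps = _find_reasonable_step(logp_grad, z, logp, grad, inv_mass, rng)
                    da = _DualAveraging(mu=math.log(10.0 * eps))
            if it == n_warmup - 1:
                eps = math.exp(da.log_eps_bar)
        else:
            k = it - n_warmup
            samples[k] = z
            accept_stats[k] = accept_prob
            tree_depths[k] = depth
            if diverged:
                divergences += 1

    return {
        "samples": samples,
        "accept_stat": accept_stats,
        "tree_depth": tree_depths,
        "divergences": divergences,
        "step_size": eps,
        "inv_mass": inv_mass,
    }


def split_rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction factor (classic, not rank-normalized).

    ``chains`` is (n_chains, n_draws); each chain is split in half, and the
    usual between/within variance ratio is computed on the 2*n_chains half
    chains.  Returns NaN (with a warning) when the within-chain variance is
    zero.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    n = chains.shape[1]
    if n < 4:
        raise ValueError("need at least 4 draws per chain to split")
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        import warnings

        warnings.warn("zero within-chain variance; split R-hat undefined")
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
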