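"""Harvest probabilities and risk ratios from recovery and reporting rates.

Harvest probability h is the recovery probability f corrected for the
probability that a hunter reports a recovered band (lambda).  In the early
era a single reporting rate applies (h = f / lambda); in the recent era
reporting differs between Canada and the USA, so the correction is
weighted by where the recoveries occur:

    h = f * (P_CAN / lambda_CAN + (1 - P_CAN) / lambda_USA)

Applied per posterior draw so credible intervals propagate.  Risk ratios
compare a late-era h against an early-era h per draw; ratios above one
indicate increased harvest pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReportingRates", "harvest_pre", "harvest_recent", "risk_ratio",
           "HarvestSurface", "build_surface"]


@dataclass(frozen=True)
class ReportingRates:
    """External band-reporting probabilities (reward-band estimates).

    ``lambda_pre`` applies to the early era with no jurisdictional
    variation; ``lambda_can``/``lambda_usa`` apply to the recent era.
    """

    lambda_pre: float = 0.43
    lambda_can: float = 0.50
    lambda_usa: float = 0.73

    def __post_init__(self):
        for name in ("lambda_pre", "lambda_can", "lambda_usa"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")


def _check_lambda(lam: float, name: str) -> None:
    if lam <= 0:
        raise ValueError(f"{name} must be > 0")


def harvest_pre(f, lambda_pre: float):
    """Early-era harvest probability f / lambda (single reporting rate).

    Values above 1 are returned unclipped with a warning: they diagnose a
    reporting rate inconsistent with the recovery probabilities.
    """
    _check_lambda(lambda_pre, "lambda_pre")
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f must lie in [0, 1]")
    h = f / lambda_pre
    if np.any(h > 1):
        warnings.warn("harvest probability exceeds 1; lambda_pre is likely "
                      "inconsistent with f", stacklevel=2)
    return h if h.ndim else float(h)


def harvest_recent(f, p_can, lambda_can: float, lambda_usa: float):
    """Recent-era harvest probability with jurisdiction-weighted reporting."""
    _check_lambda(lambda_can, "lambda_can")
    _check_lambda(lambda_usa, "lambda_usa")
    f = np.asarray(f, dtype=float)
    p_can = np.asarray(p_can, dtype=float)
    if np.any((f < 0) | (f > 1)) or np.any((p_can < 0) | (p_can > 1)):
        raise ValueError("f and p_can must lie in [0, 1]")
    h = f * (p_can / lambda_can + (1.0 - p_can) / lambda_usa)
    if np.any(h > 1):
        warnings.warn("harvest probability exceeds 1; reporting rates are "
                      "likely inconsistent with f", stacklevel=2)
    return h if h.ndim else float(h)


def risk_ratio(h_late, h_early):
    """Elementwise late/early harvest ratio across matched posterior draws.

    Draws with h_early == 0 are dropped with a warning and the ratio is
    reported on the remaining draws.
    """
    h_late = np.asarray(h_late, dtype=float)
    h_early = np.asarray(h_early, dtype=float)
    zero = h_early == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} draws with zero early-era harvest "
                      "excluded from the risk ratio", stacklevel=2)
        return h_late[~zero] / h_early[~zero]
    out = h_late / h_early
    return out if out.ndim else float(out)


@dataclass
class HarvestSurface:
    """Per block x age posterior summaries of f, P_CAN, h, and risk ratios."""

    table: pd.DataFrame
    reference_years: tuple
    rates: ReportingRates

    def __post_init__(self):
        rr = self.table["risk_ratio_mean"]
        if np.any(rr <= 0):
            raise ValueError("risk ratios must be positive")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _summaries(draws: np.ndarray, prefix: str) -> dict:
    q = np.percentile(draws, [2.5, 97.5], axis=0)
    return {f"{prefix}_mean": draws.mean(axis=0),
            f"{prefix}_lo": q[0], f"{prefix}_hi": q[1]}


def build_surface(recovery_draws, canada_draws, rates: ReportingRates,
                  years: tuple, early_band_type: str | None = None,
                  late_band_type: str | None = None,
                  rng=None) -> HarvestSurface:
    """Block-level harvest surfaces for an early and a late reference year.

    ``recovery_draws`` and ``canada_draws`` are PosteriorDraws from the two
    submodels fitted on the same block grid.  The early-year surface uses
    the single pre-era reporting rate (P_CAN cancels); the late year uses
    the jurisdiction-weighted form with f and P_CAN paired by draw index.
    Band types default to the first (early) and last (late) in the grid.
    """
    from .model import predict_probability

    rspec, cspec = recovery_draws.spec, canada_draws.spec
    if rspec.blocks != cspec.blocks:
        raise ValueError("recovery and canada fits use different block grids")
    early_year, late_year = years
    early_bt = early_band_type or rspec.band_types[0]
    late_bt = late_band_type or rspec.band_types[-1]

    n_draws = min(recovery_draws.n_chains * recovery_draws.n_draws,
                  canada_draws.n_chains * canada_draws.n_draws)
    rows = []
    for age in rspec.ages:
        f_early = predict_probability(recovery_draws, rspec, early_year, age,
                                      early_bt, rng=rng)[:n_draws]
        f_late = predict_probability(recovery_draws, rspec, late_year, age,
                                     late_bt, rng=rng)[:n_draws]
        p_can = predict_probability(canada_draws, cspec, late_year, age,
                                    late_bt, rng=rng)[:n_draws]
        h_early = harvest_pre(f_early, rates.lambda_pre)
        h_late = harvest_recent(f_late, p_can, rates.lambda_can, rates.lambda_usa)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.where(h_early > 0, h_late / np.where(h_early > 0, h_early, 1.0), np.nan)
        cols = {}
        for name, arr in (("f_early", f_early), ("f_late", f_late),
                          ("p_can", p_can), ("h_early", h_early),
                          ("h_late", h_late), ("risk_ratio", rr)):
            cols.update(_summaries(arr, name))
        blocks = np.asarray(rspec.blocks)
        df = pd.DataFrame(cols)
        df.insert(0, "age", age)
        df.insert(0, "lon_bin", blocks[:, 1])
        df.insert(0, "lat_bin", blocks[:, 0])
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    return HarvestSurface(table=table, reference_years=(early_year, late_year),
                          rates=rates)
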