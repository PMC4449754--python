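"""Posterior summary tables, annual prediction series, and map exports.

Export functions are pure serialization: every number written comes from a
posterior summary already computed upstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelSpec, PosteriorDraws, predict_probability

__all__ = ["summary_table", "annual_series", "export_maps", "blocks_to_geojson"]

_SUMMARY_PARAMS = ("alpha", "beta", "tau", "rho", "sigma_z", "sigma_e", "theta")


def _labels(name: str, spec: ModelSpec, shape: tuple) -> list:
    if name == "alpha":
        return [f"alpha[{age},{bt}]" for age in spec.ages for bt in spec.band_types]
    if name == "beta":
        return [f"beta[{cov},{age}]" for cov in spec.covariate_names for age in spec.ages]
    if name == "tau":
        return [f"tau[{age}]" for age in spec.ages]
    n = int(np.prod(shape)) if shape else 1
    return [name] if n == 1 else [f"{name}[{j}]" for j in range(n)]


def _ess_proxy(chains: np.ndarray) -> float:
    """Crude effective-sample proxy from lag-1 autocorrelation per chain."""
    m, n = chains.shape
    rhos = []
    for c in range(m):
        x = chains[c] - chains[c].mean()
        denom = float(x @ x)
        if denom == 0:
            return float("nan")
        rhos.append(float(x[:-1] @ x[1:]) / denom)
    rho = np.clip(np.mean(rhos), -0.999, 0.999)
    return m * n * (1 - rho) / (1 + rho)


def summary_table(draws: PosteriorDraws, params: tuple = _SUMMARY_PARAMS) -> pd.DataFrame:
    """Posterior mean, SD, quantiles, split R-hat and an ESS proxy per parameter."""
    from .sampler import split_rhat

    rows = []
    for name in params:
        a = draws.params[name]
        flat = a.reshape(a.shape[0], a.shape[1], -1)
        for j, label in enumerate(_labels(name, draws.spec, a.shape[2:])):
            x = flat[:, :, j]
            pooled = x.ravel()
            q = np.percentile(pooled, [2.5, 50, 97.5])
            rows.append({
                "parameter": label,
                "mean": pooled.mean(), "sd": pooled.std(ddof=1),
                "q2.5": q[0], "q50": q[1], "q97.5": q[2],
                "rhat": split_rhat(x), "ess": _ess_proxy(x),
            })
    return pd.DataFrame(rows)


def annual_series(draws: PosteriorDraws, spec: ModelSpec,
                  band_type_mix: pd.DataFrame | np.ndarray,
                  blocks=None) -> pd.DataFrame:
    """Year-by-age posterior summaries of the band-type-weighted probability.

    ``band_type_mix`` gives, per year, the proportion of each band type in
    the sample (rows must sum to 1 within 1e-6); predictions per band type
    are averaged with those weights, then over the requested blocks, per
    posterior draw.
    """
    mix = np.asarray(band_type_mix if not isinstance(band_type_mix, pd.DataFrame)
                     else band_type_mix[list(spec.band_types)], dtype=float)
    if mix.shape != (len(spec.years), len(spec.band_types)):
        raise ValueError(f"band_type_mix must be (n_years, n_band_types) = "
                         f"({len(spec.years)}, {len(spec.band_types)})")
    if np.any(np.abs(mix.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("band-type mix rows must sum to 1")
    rows = []
    for a, age in enumerate(spec.ages):
        for t, year in enumerate(spec.years):
            acc = 0.0
            for b, bt in enumerate(spec.band_types):
                if mix[t, b] == 0.0:
                    continue
                p = predict_probability(draws, spec, year, age, bt, blocks=blocks)
                acc = acc + mix[t, b] * p.mean(axis=1)  # average over blocks per draw
            q = np.percentile(acc, [2.5, 97.5])
            rows.append({"year": year, "age": age, "mean": float(np.mean(acc)),
                         "lo": float(q[0]), "hi": float(q[1])})
    return pd.DataFrame(rows)


def blocks_to_geojson(table: pd.DataFrame) -> dict:
    """GeoJSON FeatureCollection: one 1-degree square polygon per table row.

    Rows need ``lat_bin``/``lon_bin``; every other column becomes a feature
    property.  Ordering follows the table, so output is deterministic.
    """
    features = []
    props_cols = [c for c in table.columns if c not in ("lat_bin", "lon_bin")]
    for row in table.itertuples(index=False):
        lat, lon = float(row.lat_bin), float(row.lon_bin)
        ring = [[lon, lat], [lon + 1, lat], [lon + 1, lat + 1], [lon, lat + 1], [lon, lat]]
        props = {c: getattr(row, c) for c in props_cols}
        props = {k: (float(v) if isinstance(v, (np.floating, np.integer)) else v)
                 for k, v in props.items()}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"lat_bin": int(lat), "lon_bin": int(lon), **props},
        })
    return {"type": "FeatureCollection", "features": features}


def export_maps(table: pd.DataFrame, path_prefix) -> tuple[Path, Path]:
    """Write a block-level table as a CSV plus a GeoJSON twin.

    Returns the two paths written.  Serialization only; no recomputation.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    geo_path = prefix.with_suffix(".geojson")
    try:
        table.to_csv(csv_path, index=False)
        geo_path.write_text(json.dumps(blocks_to_geojson(table)))
    except OSError as exc:
        raise OSError(f"failed to write map outputs under {prefix}: {exc}") from exc
    return csv_path, geo_path
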