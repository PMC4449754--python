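#!/usr/bin/env python
"""Derive block-level harvest probabilities and risk ratios.

Combines the recovery and Canada-proportion posteriors with external
reporting probabilities: the early reference year uses the single pre-era
rate (h = f / lambda), the late year the jurisdiction-weighted correction.
Writes the harvest surface table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from duckharvest import model
from duckharvest.harvest import ReportingRates, build_surface
from duckharvest.ingest import CountCube

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--lambda-pre", type=float, default=0.43)
    ap.add_argument("--lambda-can", type=float, default=0.50)
    ap.add_argument("--lambda-usa", type=float, default=0.73)
    ap.add_argument("--early-year", type=int, default=None)
    ap.add_argument("--late-year", type=int, default=None)
    args = ap.parse_args()

    cube = CountCube.from_csv(RESULTS / "cube.csv")
    covariates = pd.read_csv(RESULTS / "covariates.csv")
    rspec = model.build_spec(cube, covariates, "recovery")
    cspec = model.build_spec(cube, covariates, "canada")
    rdraws = model.load_draws(RESULTS / "recovery_draws.npz", rspec)
    cdraws = model.load_draws(RESULTS / "canada_draws.npz", cspec)

    early = args.early_year or cube.years[len(cube.years) // 4]
    late = args.late_year or cube.years[-1]
    rates = ReportingRates(args.lambda_pre, args.lambda_can, args.lambda_usa)
    surface = build_surface(rdraws, cdraws, rates, years=(early, late))
    surface.to_csv(RESULTS / "harvest_surface.csv")

    t = surface.table
    for age in t.age.unique():
        s = t[t.age == age]
        print(f"{age}: h({early}) {s.h_early_mean.min():.3f}-{s.h_early_mean.max():.3f}, "
              f"h({late}) {s.h_late_mean.min():.3f}-{s.h_late_mean.max():.3f}, "
              f"risk ratio mean {s.risk_ratio_mean.mean():.3f} "
              f"({s.risk_ratio_mean.min():.3f}-{s.risk_ratio_mean.max():.3f})")
    print("wrote harvest_surface.csv")


if __name__ == "__main__":
    main()
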