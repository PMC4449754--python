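#!/usr/bin/env python
"""Extended credible-interval calibration study (20 replicates).

The default test suite runs a 5-replicate smoke version of this check; this
script runs the full 20-replicate study (roughly an hour on one CPU) and
prints per-parameter and overall 95%-interval coverage of the generating
values.

Usage: python scripts/coverage_extended.py [--reps 20] [--seed 0]
"""

import argparse

import numpy as np

from duckharvest import model, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--reps", type=int, default=20)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    ss = np.random.SeedSequence(args.seed)
    covered = {}
    for rep in range(args.reps):
        dseed, fseed = (int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(2))
        truth = simulate.TruthConfig(n_blocks=30, years=(1970, 1979),
                                     changepoint=1975, seed=dseed)
        cube, rec = simulate.simulate_cube(truth)
        spec = model.build_spec(cube, rec["covariates"], "recovery")
        draws = model.fit(spec, n_chains=2, n_warmup=200, n_iter=300, seed=fseed)
        for name in ("alpha", "beta"):
            est = draws.stacked(name)
            lo, hi = np.percentile(est, [2.5, 97.5], axis=0)
            hit = (rec[name] >= lo) & (rec[name] <= hi)
            covered.setdefault(name, []).append(hit.ravel())
        done = sum(len(v) for v in covered.values())
        print(f"rep {rep + 1}/{args.reps} done")
    total_hits = total_n = 0
    for name, rows in covered.items():
        arr = np.array(rows)
        print(f"{name}: coverage {arr.mean():.3f} over {arr.size} pairs")
        total_hits += arr.sum()
        total_n += arr.size
    print(f"overall 95%-interval coverage: {total_hits / total_n:.3f} "
          f"({total_hits}/{total_n}); target >= 0.85")


if __name__ == "__main__":
    main()
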