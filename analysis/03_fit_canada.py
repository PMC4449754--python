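#!/usr/bin/env python
"""Fit the proportion-recovered-in-Canada submodel.

Same machinery as the recovery fit, with trials = direct recoveries and
successes = recoveries reported in Canada.
"""

import argparse
import importlib.util
from pathlib import Path

_spec = importlib.util.spec_from_file_location(
    "fit_recovery", Path(__file__).with_name("02_fit_recovery.py"))
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--chains", type=int, default=4)
    ap.add_argument("--warmup", type=int, default=250)
    ap.add_argument("--iters", type=int, default=500)
    ap.add_argument("--seed", type=int, default=1)
    _mod.run("canada", ap.parse_args())


if __name__ == "__main__":
    main()
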