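#!/usr/bin/env python
"""Derive the hyper-apoB cutoff and rank the LDL-size surrogates.

On the synthetic healthy cohort from step 01: fits non-HDL-C on apoB,
inverts the fit at the consensus high non-HDL-C threshold (170 mg/dL)
to find the corresponding apoB level, and floors it to a clinically
usable multiple of 10 — the route by which 110 mg/dL became the apoB
cutoff.  Also ranks TG against the LDL-C/apoB ratio as correlates of
LDL particle size; TG should win on |r| (≈ −0.52 vs ≈ +0.44), which is
why TG serves as the size axis of the window.  Writes
``results/cutoff_derivation.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from ldlwindow import (compare_size_surrogates, derive_panels, fit_linear,
                       invert_regression_at, propose_cutoff, read_panels)

OUT = Path(__file__).resolve().parent.parent / "results"


def main(threshold: float) -> None:
    panels = derive_panels(read_panels(OUT / "panels_healthy.csv"))
    fit = fit_linear(panels["apob"], panels["non_hdl_c"])
    inverted = invert_regression_at(fit, threshold)
    cutoff = propose_cutoff(inverted)
    print(f"non-HDL-C = {fit.slope:.3f} x apoB + {fit.intercept:.2f} "
          f"(R^2 = {fit.r_squared:.3f}, n = {fit.n})")
    print(f"non-HDL-C {threshold:g} mg/dL corresponds to apoB {inverted:.1f} mg/dL")
    print(f"proposed hyper-apoB cutoff: {cutoff:g} mg/dL")

    cmp = compare_size_surrogates(panels)
    for name in cmp.ranking:
        print(f"r({name}, LDL size) = {cmp.correlations[name]:+.3f}")
    print(f"strongest size surrogate: {cmp.winner}")

    pd.DataFrame({
        "quantity": ["slope", "intercept", "r_squared", "apob_at_threshold",
                     "proposed_cutoff", "r_tg_size", "r_ratio_size"],
        "value": [fit.slope, fit.intercept, fit.r_squared, inverted, cutoff,
                  cmp.correlations["tg"], cmp.correlations["ldl_apob_ratio"]],
    }).to_csv(OUT / "cutoff_derivation.csv", index=False)


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--non-hdl-threshold", type=float, default=170.0)
    main(parser.parse_args().non_hdl_threshold)
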