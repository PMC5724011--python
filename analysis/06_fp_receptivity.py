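#!/usr/bin/env python
"""Receptive-site decay from fluorescence polarization.

Simulates polarization time courses for two allotype-like decay
profiles after ligand hydrolysis, converts them to millipolarization,
and reports the baseline-subtracted loss of binding sites and the raw
polarization ratio at key times.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hdxdiff.fp import polarization_ratio, simulate_fp_series

TIMES_H = [0.0, 4.0, 24.0, 46.0, 65.0]
PROFILES = {
    # (phase end h, decay rate 1/h): stable ~2 days, then rapid loss
    "allotype_A": ((24.0, 0.0017), (46.0, 0.0040), (np.inf, 0.085)),
    "allotype_B": ((24.0, 0.0044), (46.0, 0.0031), (np.inf, 0.185)),
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, phases in PROFILES.items():
        s = simulate_fp_series(TIMES_H, mP_initial=250.0, phase_rates=phases,
                               noise_mP=1.0, seed=args.seed, label=label)
        losses = s.losses()
        for t, mp, loss in zip(s.time_h, s.mP, losses):
            rows.append({"allotype": label, "time_h": t, "mP": mp,
                         "loss_percent": 100 * loss,
                         "ratio_percent": 100 * polarization_ratio(mp, s.mP[0])})
        print(f"{label}: {100*losses[2]:.1f}% of binding sites lost at 24 h, "
              f"{100*losses[3]:.1f}% at 46 h; polarization at 65 h is "
              f"{100*polarization_ratio(s.mP[4], s.mP[0]):.0f}% of initial")
    pd.DataFrame(rows).to_csv(args.out / "fp_receptivity.csv", index=False,
                              float_format="%.4g")


if __name__ == "__main__":
    main()
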