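#!/usr/bin/env python
"""Fit per-day R2* and fiber-angle maps (condition-blind stage).

Reads the study written by 01_simulate_study.py, fits the mono-exponential
R2* model to every day's multi-echo series and the diffusion tensor to every
day's DWI, and writes the quantitative maps (R2*, theta, FA) as NIfTI under
scratch/run/maps/.  No condition labels are used at this stage.
"""

import argparse
from pathlib import Path

import numpy as np

from qrelax.pipeline import StudyConfig, compute_maps

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--study", type=Path, default=ROOT / "scratch" / "study")
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "run")
    parser.add_argument("--method", default="loglinear", choices=["loglinear", "nlls"])
    args = parser.parse_args()

    cfg = StudyConfig(str(args.study), str(args.out), method=args.method)
    manifest, r2_maps, theta_maps, fa_maps = compute_maps(cfg)
    for day in sorted(r2_maps):
        m = r2_maps[day]
        inside = m.valid
        print(f"day {day:2d}: median R2* {np.median(m.r2star[inside]):6.2f} 1/s, "
              f"{int(inside.sum())} fitted voxels")
    print(f"maps under {args.out / 'maps'}")


if __name__ == "__main__":
    main()
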