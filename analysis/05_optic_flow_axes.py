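#!/usr/bin/env python
"""Which self-motion does the T4 PD field sense best?

Compares the dense T4 PD field from step 04 against the ideal optic-flow
fields of the cardinal self-motions (yaw, roll, pitch rotations; thrust,
side-slip, lift translations), then grid-searches 10,356 axes for the
optimal rotation and translation axes.  Writes results/tables/axes.json.
"""

import argparse
import json
from pathlib import Path
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from eyemapper import SyntheticConfig
from eyemapper.eye import to_eye_coords
from eyemapper.mapping import TangentVectorField
from eyemapper.opticflow import (
    angular_difference, cardinal_axes, optimal_axis, rotation_flow,
    translation_flow,
)
from eyemapper.pipeline import build_world, t4_pd_field


def main():
    ap = argparse.ArgumentParser()
    root = Path(__file__).resolve().parents[1]
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-axes", type=int, default=10356)
    ap.add_argument("--out", type=Path, default=root / "results" / "tables")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SyntheticConfig(seed=args.seed)
    world = build_world(cfg)
    _, dense = t4_pd_field(cfg, world, pd_angle_deg=0.0)

    report = {"n_axes": args.n_axes, "cardinal": {}}
    for name, axis in cardinal_axes().items():
        flow = (rotation_flow if axis.mode == "rotation" else translation_flow)(
            world.ommatidia, axis.axis)
        ang = angular_difference(dense, flow)
        report["cardinal"][name] = {
            "median_deg": float(np.nanmedian(ang)),
            "q25_deg": float(np.nanquantile(ang, 0.25)),
            "q75_deg": float(np.nanquantile(ang, 0.75)),
        }
        print(f"  vs {name:14s}: median {np.nanmedian(ang):6.1f} deg "
              f"[{np.nanquantile(ang, .25):5.1f}, {np.nanquantile(ang, .75):5.1f}]")

    print("  (a median near 180 deg means the field matches that self-motion "
          "with the opposite sign, e.g. yaw of the opposite handedness)")
    for mode in ("rotation", "translation"):
        res = optimal_axis(dense, mode, n_axes=args.n_axes)
        az, el = to_eye_coords(res.best.axis)
        report[f"optimal_{mode}"] = {
            "axis_xyz": [float(x) for x in res.best.axis],
            "azimuth_deg": float(az), "elevation_deg": float(el),
            "mean_error_deg": float(res.error_deg),
            "resolution_deg": float(res.resolution_deg),
        }
        print(f"optimal {mode} axis: azimuth {az:+.1f} deg, "
              f"elevation {el:+.1f} deg, mean error {res.error_deg:.1f} deg")

    with open(args.out / "axes.json", "w") as f:
        json.dump(report, f, indent=1)
    print(f"wrote {args.out / 'axes.json'}")


if __name__ == "__main__":
    main()
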