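#!/usr/bin/env python
"""Ommatidia viewing directions and the geometry of the eye's sampling.

From the lens/photoreceptor-tip pairs of step 01: compute viewing
directions, smooth them (50/50 neighbour rule), validate the automated
lattice indexing against the generator's coordinates, and measure per-
hexagon geometry (inter-ommatidial angles, shear, aspect ratio).  Writes
results/tables/ommatidia_geometry.csv with Mollweide map coordinates.
"""

import argparse
from pathlib import Path
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from eyemapper import SyntheticConfig
from eyemapper.eye import OmmatidiaSet, hexagon_metrics_all, ommatidium_direction, smooth_directions, to_eye_coords
from eyemapper.hexgrid import align_lattices, assign_lattice_coords
from eyemapper.projections import mollweide


def main():
    ap = argparse.ArgumentParser()
    root = Path(__file__).resolve().parents[1]
    ap.add_argument("--data", type=Path, default=root / "results" / "data")
    ap.add_argument("--out", type=Path, default=root / "results" / "tables")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pairs = pd.read_csv(args.data / "lens_tip.csv")
    lens = pairs[["lens_x", "lens_y", "lens_z"]].to_numpy()
    tip = pairs[["tip_x", "tip_y", "tip_z"]].to_numpy()
    dirs = ommatidium_direction(lens, tip)
    coords = pairs[["h", "v"]].to_numpy(int)

    # automated lattice indexing on the lens cloud, checked against the
    # generator's coordinates (the bulk should agree; the degenerate dorsal
    # cap, where row spacing collapses, is reported separately)
    rec = assign_lattice_coords(lens)
    frac_assigned = rec.assigned.mean()
    frac_match = align_lattices(rec.coords[rec.assigned], coords[rec.assigned])
    el = np.degrees(np.arcsin(np.clip(dirs[:, 2], -1, 1)))
    bulk = rec.assigned & (el < 55.0)
    frac_bulk = align_lattices(rec.coords[bulk], coords[bulk])

    omm = OmmatidiaSet(ids=pairs["id"].to_numpy(), directions=dirs,
                       coords=coords, assigned=np.ones(len(pairs), bool),
                       equator_row=(coords[:, 1] == 0),
                       central_meridian=(coords[:, 0] == 0))
    omm = smooth_directions(omm)
    az, elv = to_eye_coords(omm.directions)
    mx, my = mollweide(az, elv)

    metrics = hexagon_metrics_all(omm)
    out = omm.to_frame().merge(metrics, on="id")
    out["azimuth_deg"], out["elevation_deg"] = az, elv
    out["mollweide_x"], out["mollweide_y"] = mx, my
    out.to_csv(args.out / "ommatidia_geometry.csv", index=False)

    valid = metrics[metrics["valid"]]
    print(f"{len(omm)} ommatidia; field of view azimuth "
          f"[{az.min():.0f}, {az.max():.0f}] deg, elevation "
          f"[{elv.min():.0f}, {elv.max():.0f}] deg")
    print(f"lattice indexing: {frac_assigned:.1%} assigned, "
          f"{frac_match:.1%} matching ground truth "
          f"({frac_bulk:.1%} below 55 deg elevation)")
    print(f"inter-ommatidial angle: median {valid.delta_phi.median():.2f} deg")
    print(f"shear angle: median {valid.shear_alpha.median():.1f} deg, "
          f"IQR [{valid.shear_alpha.quantile(.25):.1f}, "
          f"{valid.shear_alpha.quantile(.75):.1f}] around 90")
    print(f"aspect ratio: median {valid.aspect_ratio.median():.3f} "
          f"(regular hexagon: {2/np.sqrt(3):.3f})")
    print(f"wrote {args.out / 'ommatidia_geometry.csv'}")


if __name__ == "__main__":
    main()
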