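"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything downstream — lattice indexing, dendrite morphometrics, eye
geometry, kernel-regression mapping, optic-flow search — can be exercised on
data from this module, with ground truth recorded for recovery tests.

What is emulated
----------------
* **Eye lattice**: ~750 viewing directions on a partial sphere (no posterior
  wedge, nothing below the ventral limit), arranged as a hexagonal lattice of
  constant-elevation rows.  A planted shear field tilts the rows: dorsal rows
  bow dorsally away from the central meridian and ventral rows ventrally, so
  the shear angle α between the +h and +v axes is < 90° in the fronto-dorsal
  and posterior-ventral quadrants and > 90° in the other two, with columns
  (the +v axis) staying exactly meridional.  The planted α is recorded per
  ommatidium.
* **Medulla column grid**: one column per ommatidium on a planar sheet,
  horizontally compressed (anterior–posterior squeeze) relative to a regular
  hexagonal lattice, mirrored along h (optic chiasm), and jittered.
* **T4-like dendrites**: binary trees spanning the unit hexagon around a home
  column, whose Strahler-2/3 branch vectors concentrate around a planted
  preferred direction.
* **Lens/tip pairs** and **cosine-tuned Poisson spike tuning curves**.

Angle conventions: degrees everywhere at the interface; the eye frame is
canonical (x front, y ipsilateral, z dorsal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .eye import OmmatidiaSet, from_eye_coords
from .hexgrid import ColumnGrid, NEIGHBOR_OFFSETS
from .skeleton import SkeletonTree, PDVector
from .stimulus import TuningCurve

__all__ = [
    "SyntheticConfig",
    "generate_eye_lattice",
    "generate_medulla_grid",
    "generate_t4_skeleton",
    "generate_lens_tip_pairs",
    "generate_tuning_data",
    "marker_band_ids",
    "SyntheticT4",
    "write_dataset",
]


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, fixed by one seed.

    The defaults are the study conditions: ~750 ommatidia at ~5° spacing,
    shear up to 15° away from 90°, a medulla squeezed along the
    anterior–posterior axis, and three stimulus repetitions.
    """

    seed: int = 0
    n_ommatidia: int = 750
    mean_spacing_deg: float = 5.0
    shear_amplitude_deg: float = 15.0     # max |α − 90°|
    medulla_anisotropy: float = 0.7       # horizontal pitch vs regular hex (=1)
    position_jitter_frac: float = 0.1     # fraction of local pitch
    n_t4: int = 180
    branch_kappa: float = 20.0            # von Mises concentration of branches
    tuning_gain_hz: float = 80.0
    tuning_baseline_hz: float = 10.0
    n_trials: int = 3

    # field of view and shear-field geometry
    azimuth_range_deg: tuple[float, float] = (-10.0, 155.0)
    elevation_range_deg: tuple[float, float] = (-70.0, 90.0)
    meridian_azimuth_deg: float = 72.5
    shear_azimuth_scale_deg: float = 45.0
    shear_elevation_scale_deg: float = 35.0
    medulla_pitch_um: float = 8.0

    def __post_init__(self):
        if self.n_ommatidia < 7:
            raise ValueError("n_ommatidia must be >= 7 (one complete hexagon)")
        if not (0.0 <= self.position_jitter_frac < 0.5):
            raise ValueError("position_jitter_frac must be in [0, 0.5)")
        if self.mean_spacing_deg <= 0:
            raise ValueError("mean_spacing_deg must be positive")
        if self.medulla_anisotropy <= 0:
            raise ValueError("medulla_anisotropy must be positive")
        if self.tuning_gain_hz < 0:
            raise ValueError("tuning_gain_hz must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for key in ("azimuth_range_deg", "elevation_range_deg"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        raw = asdict(self)
        raw["azimuth_range_deg"] = list(raw["azimuth_range_deg"])
        raw["elevation_range_deg"] = list(raw["elevation_range_deg"])
        with open(path, "w") as f:
            yaml.safe_dump(raw, f, sort_keys=False)


def planted_row_tilt(az_deg, el_deg, config: SyntheticConfig):
    """Planted tilt β of the +h axis above the local parallel, degrees.

    β = −A·tanh((az−az_c)/σ_a)·tanh(el/σ_e): zero on the equator and the
    central meridian, saturating at ±A in the four quadrants.  The planted
    shear angle is α = 90° − β.
    """
    a = np.asarray(az_deg, dtype=float)
    e = np.asarray(el_deg, dtype=float)
    return (
        -config.shear_amplitude_deg
        * np.tanh((a - config.meridian_azimuth_deg) / config.shear_azimuth_scale_deg)
        * np.tanh(e / config.shear_elevation_scale_deg)
    )


def _row_elevation_offset(az_cols: np.ndarray, e0: float,
                          config: SyntheticConfig) -> np.ndarray:
    """Elevation offset of a lattice row, integrating the planted tilt.

    Along the row the elevation obeys de/da = −tan(β(a, e0))·cos(e), with the
    cosine taken at the *actual* elevation so that the physical slope of the
    row equals the planted tilt everywhere.  The offset is zero at the
    central meridian; the ODE is marched outward in both directions with a
    midpoint rule on a 0.05° azimuth grid.
    """
    if config.shear_amplitude_deg == 0.0:
        return np.zeros_like(az_cols)
    az_c = config.meridian_azimuth_deg
    lo = min(az_cols.min(), az_c) - 1.0
    hi = max(az_cols.max(), az_c) + 1.0

    def march(direction: int) -> tuple[np.ndarray, np.ndarray]:
        end = hi if direction > 0 else lo
        n = max(2, int(abs(end - az_c) / 0.05) + 2)
        xs = np.linspace(az_c, end, n)
        es = np.empty(n)
        es[0] = e0
        for i in range(n - 1):
            da = xs[i + 1] - xs[i]
            x_mid = 0.5 * (xs[i] + xs[i + 1])
            slope = -np.tan(np.deg2rad(planted_row_tilt(x_mid, e0, config)))
            e_mid = es[i] + 0.5 * da * slope * np.cos(np.deg2rad(es[i]))
            es[i + 1] = es[i] + da * slope * np.cos(np.deg2rad(e_mid))
        return xs, es

    xs_r, es_r = march(+1)
    xs_l, es_l = march(-1)
    xs = np.concatenate([xs_l[::-1], xs_r[1:]])
    es = np.concatenate([es_l[::-1], es_r[1:]])
    return np.interp(az_cols, xs, es) - e0


def generate_eye_lattice(config: SyntheticConfig) -> OmmatidiaSet:
    """Hexagonal lattice of unit viewing directions on a partial sphere.

    Rows sit at constant base elevation (spacing s/2 per unit v); columns sit
    at constant azimuth (spacing √3/2·s per unit h, h increasing anterior).
    The planted shear field displaces row elevations; jitter (a fraction of
    the pitch, uniform in the local tangent disc) perturbs directions.  The
    ``n_ommatidia`` candidates closest to the angular centroid are kept.

    Ground truth in ``extras``: ``planted_alpha_deg``, ``planted_tilt_deg``,
    and the equatorial ``marker_band`` flag.
    """
    s = config.mean_spacing_deg
    dv = s / 2.0
    dh = (np.sqrt(3) / 2.0) * s
    az_min, az_max = config.azimuth_range_deg
    el_min, el_max = config.elevation_range_deg
    az_c = config.meridian_azimuth_deg

    v_lo = int(np.ceil(el_min / dv))
    v_hi = int(np.floor(el_max / dv))
    # h increases anterior: az(h) = az_c − h·dh
    h_lo = int(np.ceil((az_c - az_max) / dh))
    h_hi = int(np.floor((az_c - az_min) / dh))

    hs, vs, azs, els, tilts = [], [], [], [], []
    for v in range(v_lo, v_hi + 1):
        e0 = v * dv
        h_vals = np.array([h for h in range(h_lo, h_hi + 1) if (h + v) % 2 == 0])
        if len(h_vals) == 0:
            continue
        az_cols = az_c - h_vals * dh
        w = _row_elevation_offset(az_cols, e0, config)
        hs.append(h_vals)
        vs.append(np.full(len(h_vals), v))
        azs.append(az_cols)
        els.append(e0 + w)
        tilts.append(planted_row_tilt(az_cols, e0, config))
    h_all = np.concatenate(hs)
    v_all = np.concatenate(vs)
    az_all = np.concatenate(azs)
    el_all = np.concatenate(els)
    tilt_all = np.concatenate(tilts)
    if len(h_all) < config.n_ommatidia:
        raise ValueError(
            f"field of view holds only {len(h_all)} lattice sites at "
            f"{s}° spacing; reduce n_ommatidia or the spacing"
        )

    dirs = from_eye_coords(az_all, el_all)
    centroid = dirs.mean(axis=0)
    centroid /= np.linalg.norm(centroid)
    ang = np.arccos(np.clip(dirs @ centroid, -1, 1))
    order = np.lexsort((h_all, v_all, np.round(ang, 12)))
    keep = np.sort(order[: config.n_ommatidia])

    h_k, v_k = h_all[keep], v_all[keep]
    az_k, el_k = az_all[keep], el_all[keep]
    tilt_k = tilt_all[keep]

    rng = np.random.default_rng(config.seed)
    if config.position_jitter_frac > 0:
        r = config.position_jitter_frac * s * np.sqrt(rng.random(len(keep)))
        phi = 2 * np.pi * rng.random(len(keep))
        el_k = el_k + r * np.sin(phi)
        az_k = az_k + r * np.cos(phi) / np.maximum(np.cos(np.deg2rad(el_k)), 1e-6)

    directions = from_eye_coords(az_k, el_k)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    extras = {
        "planted_alpha_deg": 90.0 - tilt_k,
        "planted_tilt_deg": tilt_k,
        "marker_band": np.isin(v_k, (-1, 0, 1, 2)),
        "azimuth_deg": az_k,
        "elevation_deg": el_k,
    }
    return OmmatidiaSet(
        ids=np.arange(len(keep)),
        directions=directions,
        coords=np.column_stack([h_k, v_k]),
        assigned=np.ones(len(keep), dtype=bool),
        equator_row=(v_k == 0),
        central_meridian=(h_k == 0),
        extras=extras,
    )


def marker_band_ids(obj) -> np.ndarray:
    """Ids of the equatorial marker band (rows v ∈ {−1, 0, 1, 2}).

    These stand in for the lamina cartridges with extra photoreceptors (in
    the medulla) or the photoreceptor-chirality flip band (in the eye).
    """
    v = obj.coords[:, 1]
    return np.asarray(obj.ids)[np.isin(v, (-1, 0, 1, 2))]


def generate_medulla_grid(lattice: OmmatidiaSet, config: SyntheticConfig) -> ColumnGrid:
    """Medulla columns: one per ommatidium, on a squeezed, mirrored, jittered sheet.

    Layout: x = h_med · a·(√3/2)·p, y = v · p/2 with p the medulla pitch (µm)
    and a the anisotropy (a = 1 is a regular hexagonal lattice; the default
    a < 1 squeezes the grid along the anterior–posterior axis toward the
    45°-tilted square arrangement).  The lattice coordinate is mirrored
    (h_med = −h_eye) to emulate the optic chiasm; column ids equal ommatidium
    ids, which is the ground-truth eye map.
    """
    a = config.medulla_anisotropy
    p = config.medulla_pitch_um
    dx = a * (np.sqrt(3) / 2.0) * p
    dy = p / 2.0
    h_med = -lattice.coords[:, 0]
    v = lattice.coords[:, 1]
    pos = np.column_stack([h_med * dx, v * dy, np.zeros(len(lattice))]).astype(float)

    rng = np.random.default_rng(config.seed + 1)
    if config.position_jitter_frac > 0:
        # local pitch = nearest-neighbour distance of the ideal lattice
        pitch_local = min(p, float(np.hypot(dx, dy)))
        r = config.position_jitter_frac * pitch_local * np.sqrt(rng.random(len(lattice)))
        phi = 2 * np.pi * rng.random(len(lattice))
        pos[:, 0] += r * np.cos(phi)
        pos[:, 1] += r * np.sin(phi)

    return ColumnGrid(
        ids=lattice.ids.copy(),
        positions=pos,
        coords=np.column_stack([h_med, v]),
        assigned=np.ones(len(lattice), dtype=bool),
        equator_row=(v == 0),
        central_meridian=(h_med == 0),
        mirrored_h=True,
    )


# ---------------------------------------------------------------------------
# T4-like dendrites
# ---------------------------------------------------------------------------

@dataclass
class SyntheticT4:
    """A generated dendrite with its planted ground truth."""

    tree: SkeletonTree
    home_coord: tuple[int, int]
    pd_angle_deg: float        # planted PD, measured from local +h toward +v
    pd_direction: np.ndarray   # planted PD as a 3D unit vector in medulla space
    cell_id: int | None = None


def _local_axes(grid: ColumnGrid, home: tuple[int, int]):
    """(e_h, e_v) unit vectors of the local lattice axes at a column."""
    idx = grid.coord_index
    i = idx.get((int(home[0]), int(home[1])))
    if i is None:
        raise KeyError(f"home column {home} not in grid")
    nbr = {}
    for dh, dv in NEIGHBOR_OFFSETS:
        j = idx.get((home[0] + dh, home[1] + dv))
        if j is None:
            raise ValueError(f"home column {home} lacks a complete neighbour ring")
        nbr[(dh, dv)] = grid.positions[j]
    right = 0.5 * (nbr[(1, 1)] + nbr[(1, -1)])
    left = 0.5 * (nbr[(-1, 1)] + nbr[(-1, -1)])
    top, bottom = nbr[(0, 2)], nbr[(0, -2)]
    e_h = right - left
    e_h = e_h / np.linalg.norm(e_h)
    e_v = top - bottom
    e_v = e_v - (e_v @ e_h) * e_h
    e_v = e_v / np.linalg.norm(e_v)
    pitch = float(np.mean([np.linalg.norm(nbr[o] - grid.positions[i])
                           for o in NEIGHBOR_OFFSETS]))
    return grid.positions[i], e_h, e_v, pitch


def generate_t4_skeleton(
    grid: ColumnGrid,
    home: tuple[int, int],
    pd_angle_deg: float,
    config: SyntheticConfig,
    cell_id: int | None = None,
) -> SyntheticT4:
    """A T4-like binary dendritic tree with a planted preferred direction.

    A depth-3 binary backbone (one SN-4 stem, two SN-3, four SN-2 branches)
    runs along the planted PD; the SN-2/3 branch pairs fan out at fixed ±
    lateral angles whose contributions cancel in the vector sum, each with
    von Mises angular noise of concentration ``branch_kappa``.  SN-1 twigs
    are short and isotropic.  All nodes stay within 1.2× the unit-hexagon
    circumradius of the home column.
    """
    if config.branch_kappa <= 0:
        raise ValueError("branch_kappa must be positive")
    centre, e_h, e_v, pitch = _local_axes(grid, home)
    rng = np.random.default_rng(
        (config.seed, int(home[0]) + 2**15, int(home[1]) + 2**15,
         0 if cell_id is None else int(cell_id) + 1)
    )
    pd = np.deg2rad(pd_angle_deg)
    kappa = config.branch_kappa
    ell = pitch / 3.0
    seg_len = {"sn4": 0.9 * ell, "sn3": 1.0 * ell, "sn2": 1.0 * ell}
    lateral = {"sn3": np.deg2rad(30.0), "sn2": np.deg2rad(25.0)}

    def vm(loc):
        return rng.vonmises(loc, kappa)

    nodes_2d: list[np.ndarray] = []
    parents: list[int] = []

    def add_node(p2d, parent):
        nodes_2d.append(np.asarray(p2d, dtype=float))
        parents.append(parent)
        return len(nodes_2d) - 1

    def add_chain(start_idx, angle, length, n_interior=1):
        """Straight branch with wiggled interior nodes; returns end index."""
        p0 = nodes_2d[start_idx]
        direction = np.array([np.cos(angle), np.sin(angle)])
        normal = np.array([-direction[1], direction[0]])
        prev = start_idx
        for k in range(1, n_interior + 1):
            frac = k / (n_interior + 1)
            wig = 0.05 * length * rng.standard_normal()
            prev = add_node(p0 + frac * length * direction + wig * normal, prev)
        return add_node(p0 + length * direction, prev)

    span = seg_len["sn4"] + seg_len["sn3"] + seg_len["sn2"] + 0.4 * ell
    root_2d = -0.55 * span * np.array([np.cos(pd), np.sin(pd)])
    root = add_node(root_2d, -1)
    stem_end = add_chain(root, vm(pd), seg_len["sn4"])
    sn2_ends = []
    for sgn3 in (+1, -1):
        sn3_end = add_chain(stem_end, vm(pd + sgn3 * lateral["sn3"]), seg_len["sn3"])
        for sgn2 in (+1, -1):
            sn2_ends.append(
                add_chain(sn3_end, vm(pd + sgn2 * lateral["sn2"]), seg_len["sn2"])
            )
    for end in sn2_ends:
        for _ in range(2):
            ang1 = rng.uniform(0, 2 * np.pi)
            len1 = 0.4 * ell * rng.uniform(0.7, 1.3)
            add_chain(end, ang1, len1, n_interior=1)

    xy = np.asarray(nodes_2d)
    # containment: shrink toward the home centre if anything strays
    radii = np.linalg.norm(xy, axis=1)
    if radii.max() > 1.18 * pitch:
        xy = xy * (1.18 * pitch / radii.max())
    normal3 = np.cross(e_h, e_v)
    z_noise = 0.002 * pitch * rng.standard_normal(len(xy))
    pos3 = centre + xy[:, :1] * e_h + xy[:, 1:2] * e_v + z_noise[:, None] * normal3

    tree = SkeletonTree(
        node_ids=np.arange(1, len(xy) + 1),
        positions=pos3,
        parent=np.asarray(parents, dtype=int),
    )
    pd3 = np.cos(pd) * e_h + np.sin(pd) * e_v
    return SyntheticT4(tree=tree, home_coord=(int(home[0]), int(home[1])),
                       pd_angle_deg=float(pd_angle_deg),
                       pd_direction=pd3 / np.linalg.norm(pd3), cell_id=cell_id)


# ---------------------------------------------------------------------------
# lens/tip pairs & tuning curves
# ---------------------------------------------------------------------------

def generate_lens_tip_pairs(
    lattice: OmmatidiaSet,
    r_lens: float = 180.0,
    r_tip: float = 160.0,
    noise: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired lens/photoreceptor-tip points for each true viewing direction.

    Lens at ``r_lens·d`` (µm); tip at ``r_tip·d`` plus isotropic Gaussian
    noise of scale ``noise`` µm.  ``r_lens > r_tip > 0`` is required (the
    lens sits outside the photoreceptor tips).
    """
    if not (r_lens > r_tip > 0):
        raise ValueError("require r_lens > r_tip > 0")
    rng = np.random.default_rng(seed)
    d = lattice.directions
    lens = r_lens * d
    tip = r_tip * d + noise * rng.standard_normal(d.shape)
    return pd.DataFrame(
        {
            "id": lattice.ids,
            "lens_x": lens[:, 0], "lens_y": lens[:, 1], "lens_z": lens[:, 2],
            "tip_x": tip[:, 0], "tip_y": tip[:, 1], "tip_z": tip[:, 2],
            "h": lattice.coords[:, 0], "v": lattice.coords[:, 1],
        }
    )


def generate_tuning_data(
    pd_deg: float,
    config: SyntheticConfig,
    cell: str | int | None = None,
    location: tuple[float, float] | None = None,
    noiseless: bool = False,
    seed_offset: int = 0,
) -> TuningCurve:
    """Cosine-tuned spiking responses to edge motion in 16 directions.

    Mean rate = baseline + gain · max(0, cos(θ − pd)); each of ``n_trials``
    repetitions draws a Poisson spike count over a 1-s window, and the curve
    stores the trial-averaged rate.  ``noiseless=True`` returns the exact
    means (the infinite-trial limit).
    """
    directions = np.arange(16) * 22.5
    mean = config.tuning_baseline_hz + config.tuning_gain_hz * np.maximum(
        0.0, np.cos(np.deg2rad(directions - pd_deg))
    )
    if noiseless:
        rates = mean
    else:
        rng = np.random.default_rng((config.seed, 97, seed_offset))
        counts = rng.poisson(np.broadcast_to(mean, (config.n_trials, 16)))
        rates = counts.mean(axis=0).astype(float)
    return TuningCurve(
        directions_deg=directions,
        rates_hz=rates,
        baseline_hz=config.tuning_baseline_hz,
        cell=cell,
        location=location,
    )


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(out_dir: str | Path, config: SyntheticConfig) -> dict:
    """Generate and write a full synthetic dataset to ``out_dir``.

    Produces ``ommatidia.csv``, ``columns.csv``, ``lens_tip.csv``, one SWC
    file per T4 under ``swc/``, ``tuning.csv`` and ``truth.json``.  Returns a
    dict of the in-memory objects for further use.
    """
    import json

    from .skeleton import write_swc

    out = Path(out_dir)
    (out / "swc").mkdir(parents=True, exist_ok=True)
    omm = generate_eye_lattice(config)
    grid = generate_medulla_grid(omm, config)
    omm.to_frame().to_csv(out / "ommatidia.csv", index=False)
    grid.to_frame().to_csv(out / "columns.csv", index=False)
    generate_lens_tip_pairs(omm, seed=config.seed + 2).to_csv(
        out / "lens_tip.csv", index=False
    )

    rng = np.random.default_rng(config.seed + 3)
    interior = [
        tuple(c) for c, ok in zip(grid.coords, grid.assigned) if ok
    ]
    interior = [
        c for c in interior
        if all((c[0] + dh, c[1] + dv) in grid.coord_index for dh, dv in NEIGHBOR_OFFSETS)
    ]
    homes = [interior[i] for i in
             rng.choice(len(interior), size=min(config.n_t4, len(interior)),
                        replace=False)]
    t4s, truth_rows = [], []
    for k, home in enumerate(homes):
        t4 = generate_t4_skeleton(grid, home, pd_angle_deg=0.0, config=config,
                                  cell_id=k)
        write_swc(t4.tree, out / "swc" / f"t4b_{k:03d}.swc")
        t4s.append(t4)
        truth_rows.append(
            dict(cell_id=k, home_h=home[0], home_v=home[1], pd_angle_deg=0.0)
        )

    curves = []
    tuning_rows = []
    for k, pd_true in enumerate((0.0, 45.0, 90.0, 135.0, 180.0)):
        c = generate_tuning_data(pd_true, config, cell=k, seed_offset=k)
        curves.append(c)
        for d, r in zip(c.directions_deg, c.rates_hz):
            tuning_rows.append(dict(cell=k, direction_deg=d, rate_hz=r,
                                    baseline_hz=c.baseline_hz,
                                    true_pd_deg=pd_true))
    pd.DataFrame(tuning_rows).to_csv(out / "tuning.csv", index=False)

    truth = {
        "config": asdict(config),
        "t4": truth_rows,
    }
    with open(out / "truth.json", "w") as f:
        json.dump(truth, f, indent=1,
                  default=lambda o: o.item() if hasattr(o, "item") else list(o))
    return {"ommatidia": omm, "columns": grid, "t4s": t4s, "tuning": curves}
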