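"""End-to-end drivers composing the synthetic world with the mapping pipeline.

These functions are the shared backbone of the analysis scripts, the test
suite and the acceptance script: build a synthetic world, recover planted
dendrite PDs, push PDs through the eye map, measure how the mapped PD field
follows the planted ommatidial shear, and search for optimal self-motion
axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eye import OmmatidiaSet, tangent_basis
from .hexgrid import ColumnGrid, NEIGHBOR_OFFSETS, reference_neighborhood
from .mapping import (
    EyeMap,
    KernelModel,
    TangentVectorField,
    interpolate_pd_field,
    map_pd_to_eye,
    match_grids,
)
from .skeleton import PDVector, pd_vector
from .synthetic import (
    SyntheticConfig,
    SyntheticT4,
    _local_axes,
    generate_eye_lattice,
    generate_medulla_grid,
    generate_t4_skeleton,
)

__all__ = [
    "SyntheticWorld",
    "build_world",
    "interior_columns",
    "planted_h_pd",
    "line_tilt_deg",
    "mechanism_experiment",
    "recover_t4_pds",
    "t4_pd_field",
]


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    ommatidia: OmmatidiaSet
    columns: ColumnGrid
    eyemap: EyeMap


def build_world(config: SyntheticConfig) -> SyntheticWorld:
    """Eye lattice + medulla grid + their one-to-one eye map."""
    omm = generate_eye_lattice(config)
    grid = generate_medulla_grid(omm, config)
    emap = match_grids(grid, omm)
    return SyntheticWorld(config=config, ommatidia=omm, columns=grid, eyemap=emap)


def interior_columns(world: SyntheticWorld, rings: int = 2) -> list[tuple[int, int]]:
    """Matched medulla coordinates whose full ``rings``-ring neighbourhood is
    matched too (the columns eligible for PD mapping)."""
    grid = world.columns
    matched_ids = set(world.eyemap.pairs)
    out = []
    for i in range(len(grid)):
        if not grid.assigned[i] or int(grid.ids[i]) not in matched_ids:
            continue
        c = (int(grid.coords[i][0]), int(grid.coords[i][1]))
        present, missing = reference_neighborhood(grid, c, rings=rings)
        if missing:
            continue
        if all(int(grid.ids[grid.coord_index[cc]]) in matched_ids for cc in present):
            out.append(c)
    return out


def planted_h_pd(world: SyntheticWorld, home: tuple[int, int],
                 span_fraction: float = 1.5) -> PDVector:
    """An exact medulla-space PD along the local +h axis at ``home``.

    ``span_fraction`` scales the head-to-tail length in local pitch units
    (1.5 ≈ the dendrite span across the unit hexagon).
    """
    centre, e_h, _, pitch = _local_axes(world.columns, home)
    L = span_fraction * pitch
    return PDVector(centre=centre, direction=e_h, length=L, width=0.6 * L,
                    home_coord=home)


def line_tilt_deg(base: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Signed tilt of tangent vectors from the local parallel of elevation.

    Line angle (mod 180°, mapped to (−90°, 90°]) between each tangent vector
    and the local east direction; the sign convention matches the planted row
    tilt (positive = the +h line climbs dorsally going anterior).
    """
    east, north = tangent_basis(base)
    # anterior = decreasing azimuth (−east); a line climbing dorsally going
    # anterior gets a positive tilt, matching the planted row-tilt convention
    x = -np.sum(vectors * east, axis=1)
    y = np.sum(vectors * north, axis=1)
    ang = np.degrees(np.arctan2(y, x))
    ang = (ang + 90.0) % 180.0 - 90.0
    return ang


def mechanism_experiment(
    config: SyntheticConfig,
    world: SyntheticWorld | None = None,
    subsample: int = 2,
    model: KernelModel | None = None,
) -> pd.DataFrame:
    """The core mechanism at desk scale: +h-aligned medulla PDs through the
    eye map reproduce the planted ommatidial shear.

    Exact +h-aligned PDs are planted at every ``subsample``-th interior
    column, mapped into eye coordinates by kernel regression, and the tilt of
    each mapped PD from the local parallel of elevation is compared with the
    planted row tilt (= 90° − planted shear angle α) at the home ommatidium.

    Returns one row per mapped PD with ``mapped_tilt_deg``,
    ``planted_tilt_deg`` and their difference.
    """
    world = world or build_world(config)
    grid, omm, emap = world.columns, world.ommatidia, world.eyemap
    if model is None:
        model = KernelModel("adaptive_nn", k=9)
    omm_row = {int(omm.ids[j]): j for j in range(len(omm))}
    rows = []
    cols = interior_columns(world)[::subsample]
    for home in cols:
        pdv = planted_h_pd(world, home)
        base, vec, span = map_pd_to_eye(pdv, emap, grid, omm, model=model)
        cid = int(grid.ids[grid.coord_index[home]])
        j = omm_row[emap.pairs[cid]]
        mapped = float(line_tilt_deg(base[None, :], vec[None, :])[0])
        planted = float(omm.extras["planted_tilt_deg"][j])
        rows.append(
            dict(h=home[0], v=home[1], ommatidium=int(omm.ids[j]),
                 mapped_tilt_deg=mapped, planted_tilt_deg=planted,
                 tilt_error_deg=mapped - planted, span_deg=span)
        )
    return pd.DataFrame(rows)


def recover_t4_pds(
    config: SyntheticConfig,
    world: SyntheticWorld | None = None,
    n: int | None = None,
    pd_angle_deg: float = 0.0,
) -> pd.DataFrame:
    """Generate T4 trees at interior columns and recover their PDs.

    Returns per-cell planted vs recovered PD angles (degrees, in the medulla
    plane) and the absolute angular error.
    """
    world = world or build_world(config)
    grid = world.columns
    n = n if n is not None else config.n_t4
    cols = interior_columns(world, rings=1)
    rng = np.random.default_rng(config.seed + 11)
    homes = [cols[i] for i in rng.choice(len(cols), size=min(n, len(cols)),
                                         replace=False)]
    rows = []
    for k, home in enumerate(homes):
        t4 = generate_t4_skeleton(grid, home, pd_angle_deg, config, cell_id=k)
        rec = pd_vector(t4.tree)
        cosang = float(np.clip(rec.direction @ t4.pd_direction, -1, 1))
        err = np.degrees(np.arccos(cosang))
        rows.append(dict(cell_id=k, home_h=home[0], home_v=home[1],
                         planted_deg=pd_angle_deg, error_deg=err,
                         length_um=rec.length, width_um=rec.width))
    return pd.DataFrame(rows)


def t4_pd_field(
    config: SyntheticConfig,
    world: SyntheticWorld | None = None,
    pd_angle_deg: float = 0.0,
    model: KernelModel | None = None,
) -> tuple[TangentVectorField, TangentVectorField]:
    """Full anatomical pipeline: T4 trees → PDs → eye map → dense PD field.

    Generates ``config.n_t4`` T4-like trees with the planted PD angle, runs
    the Strahler/PD analysis on each, maps every PD into eye coordinates, and
    interpolates a dense tangent field over all ommatidia.  Returns
    ``(sparse_field, dense_field)``.
    """
    world = world or build_world(config)
    grid, omm, emap = world.columns, world.ommatidia, world.eyemap
    if model is None:
        model = KernelModel("adaptive_nn", k=9)
    cols = interior_columns(world)
    rng = np.random.default_rng(config.seed + 13)
    homes = [cols[i] for i in rng.choice(len(cols),
                                         size=min(config.n_t4, len(cols)),
                                         replace=False)]
    bases, vecs, ids = [], [], []
    for k, home in enumerate(homes):
        t4 = generate_t4_skeleton(grid, home, pd_angle_deg, config, cell_id=k)
        pdv = pd_vector(t4.tree)
        pdv.home_coord = home
        pdv.cell_id = k
        base, vec, _ = map_pd_to_eye(pdv, emap, grid, omm, model=model)
        bases.append(base)
        vecs.append(vec)
        ids.append(k)
    sparse = TangentVectorField(base=np.asarray(bases), vectors=np.asarray(vecs),
                                ids=np.asarray(ids))
    dense = interpolate_pd_field(sparse, omm)
    return sparse, dense
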