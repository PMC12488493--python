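"""Compound-eye geometry: ommatidia viewing directions and hexagon metrics.

Each ommatidium's viewing direction is the unit vector from the photoreceptor
tip to the centre of its corneal lens.  Directions live on the unit sphere
and inherit the hexagonal lattice coordinates of the lens grid.  Per-hexagon
geometry metrics (inter-ommatidial angles ΔΦ, ΔΦ_v, ΔΦ_h, shear angle α,
aspect ratio) use the small-angle chord convention: an angle in degrees is the
Euclidean chord between unit vectors times 180/π.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hexgrid import (
    ColumnGrid,
    NEIGHBOR_OFFSETS,
    OFFSET_V1,
    OFFSET_V2,
    OFFSET_V3,
    OFFSET_V4,
    OFFSET_V5,
    OFFSET_V6,
)

__all__ = [
    "OmmatidiaSet",
    "EyeFrame",
    "HexMetrics",
    "ommatidium_direction",
    "smooth_directions",
    "hexagon_metrics",
    "hexagon_metrics_all",
    "to_eye_coords",
    "from_eye_coords",
    "estimate_eye_frame",
]

_RAD2DEG = 180.0 / np.pi


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return v / np.linalg.norm(v, axis=axis, keepdims=True)


@dataclass
class OmmatidiaSet:
    """Per-ommatidium viewing directions on the unit sphere with lattice coords."""

    ids: np.ndarray         # (n,) int
    directions: np.ndarray  # (n, 3) unit vectors
    coords: np.ndarray      # (n, 2) int [h, v]
    assigned: np.ndarray    # (n,) bool
    lens: np.ndarray | None = None   # (n, 3) µm
    tip: np.ndarray | None = None    # (n, 3) µm
    equator_row: np.ndarray | None = None
    central_meridian: np.ndarray | None = None
    extras: dict | None = None       # ground-truth columns for synthetic sets

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.directions = np.asarray(self.directions, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        self.assigned = np.asarray(self.assigned, dtype=bool)
        n = len(self.ids)
        if self.equator_row is None:
            self.equator_row = np.zeros(n, dtype=bool)
        if self.central_meridian is None:
            self.central_meridian = np.zeros(n, dtype=bool)
        if self.extras is None:
            self.extras = {}
        self._index = None

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def coord_index(self) -> dict[tuple[int, int], int]:
        if self._index is None:
            self._index = {
                (int(h), int(v)): i
                for i, ((h, v), ok) in enumerate(zip(self.coords, self.assigned))
                if ok
            }
        return self._index

    def neighbor_indices(self, i: int) -> list[int]:
        h, v = self.coords[i]
        out = []
        for dh, dv in NEIGHBOR_OFFSETS:
            j = self.coord_index.get((int(h) + dh, int(v) + dv))
            if j is not None:
                out.append(j)
        return out

    def complete_neighbour_set(self) -> np.ndarray:
        """Boolean mask: all six lattice neighbours present."""
        return np.array(
            [self.assigned[i] and len(self.neighbor_indices(i)) == 6
             for i in range(len(self))],
            dtype=bool,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "x": self.directions[:, 0],
                "y": self.directions[:, 1],
                "z": self.directions[:, 2],
                "h": self.coords[:, 0],
                "v": self.coords[:, 1],
                "assigned": self.assigned,
                "equator_row": self.equator_row,
                "central_meridian": self.central_meridian,
            }
        )
        for k, col in self.extras.items():
            df[k] = col
        return df

    def as_grid(self) -> ColumnGrid:
        """View the direction set as a ColumnGrid (positions = directions)."""
        return ColumnGrid(
            ids=self.ids,
            positions=self.directions,
            coords=self.coords,
            assigned=self.assigned,
            equator_row=self.equator_row,
            central_meridian=self.central_meridian,
        )


@dataclass
class EyeFrame:
    """Eye coordinate frame: sagittal-plane normal and equator-plane normal.

    Convention (right eye): azimuth 0 at the frontal midline, positive toward
    the ipsilateral (right) side; elevation 0 in the lens-equator plane,
    positive dorsal.
    """

    sagittal_normal: np.ndarray  # unit, points toward the ipsilateral side
    z_axis: np.ndarray           # unit, dorsal

    def __post_init__(self):
        self.sagittal_normal = np.asarray(self.sagittal_normal, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        self.sagittal_normal = self.sagittal_normal / np.linalg.norm(self.sagittal_normal)
        self.z_axis = self.z_axis / np.linalg.norm(self.z_axis)
        if abs(float(self.sagittal_normal @ self.z_axis)) > 1e-9:
            raise ValueError("sagittal normal and z axis must be orthogonal")

    @classmethod
    def canonical(cls) -> "EyeFrame":
        """x front, y right (ipsilateral for the right eye), z up."""
        return cls(np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]))

    @property
    def frontal(self) -> np.ndarray:
        """Unit vector along the frontal midline in the equator plane."""
        f = np.cross(self.sagittal_normal, self.z_axis)
        return f / np.linalg.norm(f)


def ommatidium_direction(lens: np.ndarray, tip: np.ndarray) -> np.ndarray:
    """Viewing direction: unit vector from photoreceptor tip to lens centre.

    Vectorized over leading axes; raises on coincident points.
    """
    lens = np.asarray(lens, dtype=float)
    tip = np.asarray(tip, dtype=float)
    d = lens - tip
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("lens and tip coincide; viewing direction undefined")
    return d / norm


def smooth_directions(omm: OmmatidiaSet) -> OmmatidiaSet:
    """One pass of 50/50 neighbour smoothing on the direction sphere.

    For each point with at least five lattice neighbours the new direction is
    ``normalize(0.5 * self + 0.5 * mean(neighbours))``; boundary points (fewer
    than five neighbours) are left untouched.  All updates use the original
    (pre-pass) directions.
    """
    new_dirs = omm.directions.copy()
    for i in range(len(omm)):
        if not omm.assigned[i]:
            continue
        nbr = omm.neighbor_indices(i)
        if len(nbr) < 5:
            continue
        avg = omm.directions[nbr].mean(axis=0)
        blended = 0.5 * omm.directions[i] + 0.5 * avg
        new_dirs[i] = blended / np.linalg.norm(blended)
    return OmmatidiaSet(
        ids=omm.ids.copy(),
        directions=new_dirs,
        coords=omm.coords.copy(),
        assigned=omm.assigned.copy(),
        lens=None if omm.lens is None else omm.lens.copy(),
        tip=None if omm.tip is None else omm.tip.copy(),
        equator_row=omm.equator_row.copy(),
        central_meridian=omm.central_meridian.copy(),
        extras=dict(omm.extras),
    )


@dataclass
class HexMetrics:
    """Geometry of one unit hexagon of viewing directions (degrees)."""

    delta_phi: float = np.nan     # mean chord angle to the six neighbours
    delta_phi_v: float = np.nan   # mean over the vertical pair (v1, v4)
    delta_phi_h: float = np.nan   # mean over the two side-pair midpoints
    shear_alpha: float = np.nan   # angle between the +h and +v axes
    aspect_ratio: float = np.nan  # delta_phi_v / delta_phi_h
    valid: bool = False


def hexagon_metrics(omm: OmmatidiaSet, centre) -> HexMetrics:
    """ΔΦ, ΔΦ_v, ΔΦ_h, shear α and aspect ratio for one hexagon.

    ``centre`` is a point id.  Metrics are valid only when all six lattice
    neighbours exist; otherwise a HexMetrics with ``valid=False`` and NaN
    fields is returned.

    With ``vi = neighbour_i − centre`` (chords between unit vectors):

    * ΔΦ   = mean of the six |vi|, as degrees (chord × 180/π)
    * ΔΦ_v = mean(|v1|, |v4|)
    * ΔΦ_h = mean(|(v2+v6)/2|, |(v3+v5)/2|)  (centre→side-pair-midpoint chords)
    * α    = angle between the +h axis (left-pair midpoint → right-pair
      midpoint) and the +v axis (bottom neighbour → top neighbour)
    """
    i = int(np.flatnonzero(omm.ids == int(centre))[0]) if np.isscalar(centre) else int(centre)
    h, v = int(omm.coords[i][0]), int(omm.coords[i][1])
    idx = omm.coord_index
    nbr = {}
    for name, (dh, dv) in (("v1", OFFSET_V1), ("v2", OFFSET_V2), ("v3", OFFSET_V3),
                           ("v4", OFFSET_V4), ("v5", OFFSET_V5), ("v6", OFFSET_V6)):
        j = idx.get((h + dh, v + dv))
        if j is None:
            return HexMetrics(valid=False)
        nbr[name] = omm.directions[j] - omm.directions[i]

    chords = np.array([np.linalg.norm(nbr[k]) for k in
                       ("v1", "v2", "v3", "v4", "v5", "v6")])
    delta_phi = float(chords.mean() * _RAD2DEG)
    delta_phi_v = float(0.5 * (np.linalg.norm(nbr["v1"]) + np.linalg.norm(nbr["v4"]))
                        * _RAD2DEG)
    right_mid = 0.5 * (nbr["v2"] + nbr["v6"])
    left_mid = 0.5 * (nbr["v3"] + nbr["v5"])
    delta_phi_h = float(0.5 * (np.linalg.norm(right_mid) + np.linalg.norm(left_mid))
                        * _RAD2DEG)

    h_axis = right_mid - left_mid
    v_axis = nbr["v1"] - nbr["v4"]
    cosang = float(h_axis @ v_axis / (np.linalg.norm(h_axis) * np.linalg.norm(v_axis)))
    shear_alpha = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return HexMetrics(
        delta_phi=delta_phi,
        delta_phi_v=delta_phi_v,
        delta_phi_h=delta_phi_h,
        shear_alpha=shear_alpha,
        aspect_ratio=delta_phi_v / delta_phi_h,
        valid=True,
    )


def hexagon_metrics_all(omm: OmmatidiaSet) -> pd.DataFrame:
    """Hexagon metrics for every ommatidium (NaN where incomplete)."""
    rows = []
    for i in range(len(omm)):
        m = hexagon_metrics(omm, i) if omm.assigned[i] else HexMetrics(valid=False)
        rows.append(
            dict(id=int(omm.ids[i]), delta_phi=m.delta_phi, delta_phi_v=m.delta_phi_v,
                 delta_phi_h=m.delta_phi_h, shear_alpha=m.shear_alpha,
                 aspect_ratio=m.aspect_ratio, valid=m.valid)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# eye frame & spherical coordinates
# ---------------------------------------------------------------------------

def estimate_eye_frame(
    lens_right: np.ndarray,
    lens_left: np.ndarray,
    equator_lens: np.ndarray,
    dorsal_hint: np.ndarray | None = None,
) -> EyeFrame:
    """Estimate the eye frame from the lens clouds of both eyes.

    The sagittal normal comes from bilateral symmetry (direction between the
    two eyes' lens centroids); the equator (z = 0) plane is the least-squares
    plane through the equator-row lens positions, orthogonalized against the
    sagittal normal and oriented by ``dorsal_hint`` (default +z of the input
    coordinates).
    """
    lens_right = np.asarray(lens_right, dtype=float)
    lens_left = np.asarray(lens_left, dtype=float)
    equator_lens = np.asarray(equator_lens, dtype=float)
    n_s = lens_right.mean(axis=0) - lens_left.mean(axis=0)
    n_s = n_s / np.linalg.norm(n_s)
    centred = equator_lens - equator_lens.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    z = vt[2]
    z = z - (z @ n_s) * n_s
    z = z / np.linalg.norm(z)
    hint = np.array([0.0, 0.0, 1.0]) if dorsal_hint is None else np.asarray(dorsal_hint, float)
    if z @ hint < 0:
        z = -z
    return EyeFrame(sagittal_normal=n_s, z_axis=z)


def to_eye_coords(directions: np.ndarray, frame: EyeFrame | None = None):
    """(azimuth, elevation) in degrees for unit direction vectors.

    Azimuth 0 at the frontal midline, positive ipsilateral; elevation 0 in the
    equator plane, positive dorsal.  Directions parallel to a pole get
    azimuth 0 by convention.
    """
    if frame is None:
        frame = EyeFrame.canonical()
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    x = d @ frame.frontal
    y = d @ frame.sagittal_normal
    z = np.clip(d @ frame.z_axis, -1.0, 1.0)
    el = np.degrees(np.arcsin(z))
    az = np.degrees(np.arctan2(y, x))
    az = np.where(np.isclose(np.abs(z), 1.0), 0.0, az)
    if np.ndim(directions) == 1:
        return float(az[0]), float(el[0])
    return az, el


def from_eye_coords(az_deg, el_deg, frame: EyeFrame | None = None) -> np.ndarray:
    """Inverse of :func:`to_eye_coords` (unit vectors)."""
    if frame is None:
        frame = EyeFrame.canonical()
    az = np.deg2rad(np.asarray(az_deg, dtype=float))
    el = np.deg2rad(np.asarray(el_deg, dtype=float))
    x = np.cos(el) * np.cos(az)
    y = np.cos(el) * np.sin(az)
    z = np.sin(el)
    basis = np.stack([frame.frontal, frame.sagittal_normal, frame.z_axis])
    return np.stack([x, y, z], axis=-1) @ basis


def tangent_basis(directions: np.ndarray, frame: EyeFrame | None = None):
    """Local east/north unit vectors at each direction.

    East points toward increasing azimuth along the parallel of elevation;
    north toward increasing elevation along the meridian.  Undefined at the
    poles (returns NaN rows there).
    """
    if frame is None:
        frame = EyeFrame.canonical()
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    z = frame.z_axis
    east = np.cross(z, d)
    norm = np.linalg.norm(east, axis=1, keepdims=True)
    east = np.where(norm > 1e-12, east / np.where(norm > 0, norm, 1.0), np.nan)
    north = np.cross(d, east)
    return east, north
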