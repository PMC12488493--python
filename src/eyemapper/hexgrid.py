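"""Hexagonal-lattice bookkeeping for retinotopic column grids.

Both the medulla column array and the array of ommatidia viewing directions
are hexagonal lattices in slightly deformed embeddings.  This module assigns
integer lattice coordinates to a 3D point set, locates the two global
landmarks (equator row, central meridian), enumerates the neighbourhoods used
by the kernel-regression mapping, and flattens small neighbourhoods onto a
local 2D plane.

Coordinate convention (doubled coordinates)
-------------------------------------------
A lattice site is ``(h, v)`` with the parity constraint ``h + v`` even.
The six neighbours of ``(h, v)`` are::

    v1 = (h, v+2)    top           v4 = (h, v-2)    bottom
    v2 = (h+1, v+1)  upper right   v6 = (h+1, v-1)  lower right
    v3 = (h-1, v+1)  upper left    v5 = (h-1, v-1)  lower left

Rows share ``v``; columns share ``h``.  The same scheme describes both the
nearly regular hexagonal eye lattice and the anterior-posteriorly squeezed
("square grid tilted at 45°") medulla lattice — only the embedding differs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "NEIGHBOR_OFFSETS",
    "ColumnGrid",
    "assign_lattice_coords",
    "find_landmarks",
    "reference_neighborhood",
    "ring_offsets",
    "local_flatten",
    "lattice_symmetries",
    "align_lattices",
    "regular_positions",
]

# Neighbour offsets in the angular order used throughout: v2, v1, v3, v5, v4, v6
# (counter-clockwise starting from the upper-right diagonal).
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 1),   # v2 upper right
    (0, 2),   # v1 top
    (-1, 1),  # v3 upper left
    (-1, -1),  # v5 lower left
    (0, -2),  # v4 bottom
    (1, -1),  # v6 lower right
)

# Labelled access for hexagon-metric code.
OFFSET_V1 = (0, 2)
OFFSET_V2 = (1, 1)
OFFSET_V3 = (-1, 1)
OFFSET_V4 = (0, -2)
OFFSET_V5 = (-1, -1)
OFFSET_V6 = (1, -1)


def _to_axial(h: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # axial q = h, r = (v - h) / 2 ; exact for valid parity
    return h, (v - h) // 2


def _from_axial(q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return q, 2 * r + q


@dataclass
class ColumnGrid:
    """A point set with (partial) lattice coordinates and landmark flags.

    ``coords`` holds one ``(h, v)`` pair per point; rows of ``assigned`` that
    are False carry no meaningful coordinate.  ``mirrored_h`` records the
    optic-chiasm convention: for medulla grids ``+h`` points posterior, which
    corresponds to ``-h`` (anterior) on the eye.
    """

    ids: np.ndarray                  # (n,) int
    positions: np.ndarray            # (n, 3) float, µm (or unit-sphere units)
    coords: np.ndarray               # (n, 2) int [h, v]
    assigned: np.ndarray             # (n,) bool
    equator_row: np.ndarray = None   # (n,) bool
    central_meridian: np.ndarray = None
    no_inner_photoreceptor: np.ndarray = None
    dorsal_rim: np.ndarray = None
    mirrored_h: bool = False

    def __post_init__(self):
        n = len(self.ids)
        for name in ("equator_row", "central_meridian",
                     "no_inner_photoreceptor", "dorsal_rim"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n, dtype=bool))
        self.ids = np.asarray(self.ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        self.assigned = np.asarray(self.assigned, dtype=bool)
        self._index = None

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def coord_index(self) -> dict[tuple[int, int], int]:
        """Map (h, v) -> row index, assigned points only (cached)."""
        if self._index is None:
            self._index = {
                (int(h), int(v)): i
                for i, ((h, v), ok) in enumerate(zip(self.coords, self.assigned))
                if ok
            }
        return self._index

    def invalidate_index(self) -> None:
        self._index = None

    def neighbors_of(self, idx: int) -> list[int]:
        """Row indices of the assigned lattice neighbours of point ``idx``."""
        h, v = self.coords[idx]
        out = []
        for dh, dv in NEIGHBOR_OFFSETS:
            j = self.coord_index.get((int(h) + dh, int(v) + dv))
            if j is not None:
                out.append(j)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "h": self.coords[:, 0],
                "v": self.coords[:, 1],
                "assigned": self.assigned,
                "equator_row": self.equator_row,
                "central_meridian": self.central_meridian,
                "no_inner_photoreceptor": self.no_inner_photoreceptor,
                "dorsal_rim": self.dorsal_rim,
            }
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mirrored_h: bool = False) -> "ColumnGrid":
        return cls(
            ids=df["id"].to_numpy(),
            positions=df[["x", "y", "z"]].to_numpy(float),
            coords=df[["h", "v"]].to_numpy(int),
            assigned=df["assigned"].to_numpy(bool),
            equator_row=df["equator_row"].to_numpy(bool),
            central_meridian=df["central_meridian"].to_numpy(bool),
            no_inner_photoreceptor=df["no_inner_photoreceptor"].to_numpy(bool),
            dorsal_rim=df["dorsal_rim"].to_numpy(bool),
            mirrored_h=mirrored_h,
        )


class LatticeAssignmentError(ValueError):
    """Raised when a point set cannot be indexed as a hexagonal lattice."""


def _local_generators(points: np.ndarray, tree: cKDTree, seed: int) -> tuple:
    """Estimate the two local lattice generator vectors around ``seed``.

    Displacement vectors from the ~18 points nearest the seed to each of
    their 8 nearest neighbours are projected into the local tangent plane and
    clustered by angle; jitter averages out across the cluster means.  The
    two shortest non-collinear cluster directions are the diagonal lattice
    generators ``u, v``; the third neighbour direction is the shorter of
    ``u ± v``.  Returns ``(u, v, w)`` as 3D vectors.
    """
    n = len(points)
    k_local = min(19, n)
    _, near = tree.query(points[seed], k=k_local)
    patch = np.atleast_1d(near)
    # tangent plane of the patch
    pp = points[patch]
    centre = pp.mean(axis=0)
    _, _, vt = np.linalg.svd(pp - centre, full_matrices=False)
    e1, e2 = vt[0], vt[1]

    k_nb = min(9, n)
    d_all, i_all = tree.query(points[patch], k=k_nb)
    med = np.median(d_all[:, 1])
    disp2d = []
    for row, (dd, ii) in enumerate(zip(d_all, i_all)):
        for dist, j in zip(dd[1:], ii[1:]):
            if dist < 1.6 * med:
                d3 = points[j] - points[patch[row]]
                disp2d.append([d3 @ e1, d3 @ e2])
    disp2d = np.asarray(disp2d)
    if len(disp2d) < 12:
        raise LatticeAssignmentError("too few neighbour displacements")

    lengths = np.hypot(disp2d[:, 0], disp2d[:, 1])

    def mean_shift(start_vec: np.ndarray) -> np.ndarray:
        est = start_vec.copy()
        for _ in range(6):
            en = np.linalg.norm(est)
            cosang = (disp2d @ est) / np.maximum(lengths * en, 1e-300)
            sel = (cosang > np.cos(np.deg2rad(30.0))) & (lengths < 1.45 * en)
            if sel.sum() < 3:
                break
            est = disp2d[sel].mean(axis=0)
        return est

    u2 = mean_shift(disp2d[int(np.argmin(lengths))])
    # second generator: shortest displacement well away from ±u, refined
    un = np.linalg.norm(u2)
    cos_u = np.abs(disp2d @ u2) / np.maximum(lengths * un, 1e-300)
    rest = np.flatnonzero(cos_u < np.cos(np.deg2rad(35.0)))
    if len(rest) == 0:
        raise LatticeAssignmentError("could not find two independent generators")
    v2 = mean_shift(disp2d[rest[int(np.argmin(lengths[rest]))]])
    if u2[0] * v2[1] - u2[1] * v2[0] < 0:
        v2 = -v2
    w2 = u2 - v2 if np.hypot(*(u2 - v2)) <= np.hypot(*(u2 + v2)) else u2 + v2

    def lift(d2):
        return d2[0] * e1 + d2[1] * e2

    return lift(u2), lift(v2), lift(w2), np.hypot(*u2)


def assign_lattice_coords(
    points: np.ndarray,
    seeds: Mapping[int, tuple[int, int]] | None = None,
    ids: np.ndarray | None = None,
    match_tol: float = 0.45,
) -> ColumnGrid:
    """Assign integer hexagonal lattice coordinates to a 3D point set.

    Breadth-first wavefront assignment: a seed point gets ``(0, 0)`` (or the
    caller-supplied seed coordinates), its six nearest neighbours are labelled
    in cyclic order, and the front then grows outward.  At each assigned point
    a local affine lattice model is refit from its already-assigned
    neighbourhood (least squares over lattice offsets), the six neighbour
    positions are predicted, and each prediction is matched greedily to the
    nearest unmatched point within ``match_tol`` of the local step length.
    Points that never match are reported unassigned rather than guessed.

    The absolute orientation of the recovered coordinates is arbitrary up to
    the 12-element lattice point group unless ``seeds`` pins it.

    Parameters
    ----------
    points : (n, 3) array
        Point positions; any rigid pose and global scale.
    seeds : optional mapping of point index -> (h, v)
        Known assignments; at least one interior point with one neighbour is
        needed to fix orientation (a single seed fixes only translation).
    match_tol : float
        Matching radius as a fraction of the locally predicted step length.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 7:
        raise LatticeAssignmentError("need at least 7 points (one full hexagon)")
    if ids is None:
        ids = np.arange(n)

    tree = cKDTree(points)
    k = min(7, n)
    nn_d, nn_i = tree.query(points, k=k)
    local_pitch = np.median(nn_d[:, 1:], axis=1)

    coords = np.zeros((n, 2), dtype=int)
    assigned = np.zeros(n, dtype=bool)

    # --- seed -------------------------------------------------------------
    if seeds:
        seed_items = sorted(seeds.items())
        for idx, (h, v) in seed_items:
            if (h + v) % 2 != 0:
                raise LatticeAssignmentError(f"seed {(h, v)} violates parity")
            coords[idx] = (h, v)
            assigned[idx] = True
        queue = deque(idx for idx, _ in seed_items)
        if len(seed_items) < 3:
            # orientation still free: bootstrap neighbours of the first seed
            idx = seed_items[0][0]
            _bootstrap_hexagon(points, tree, idx, coords, assigned,
                               local_pitch, base=tuple(coords[idx]))
            queue = deque(np.flatnonzero(assigned).tolist())
    else:
        centroid = points.mean(axis=0)
        seed = int(np.argmin(np.linalg.norm(points - centroid, axis=1)))
        coords[seed] = (0, 0)
        assigned[seed] = True
        _bootstrap_hexagon(points, tree, seed, coords, assigned, local_pitch)
        queue = deque(np.flatnonzero(assigned).tolist())

    coord_of = {tuple(coords[i]): i for i in range(n) if assigned[i]}

    # --- wavefront --------------------------------------------------------
    # offsets within lattice radius 2 used to fit the local affine model
    fit_offsets = [(0, 0)] + list(NEIGHBOR_OFFSETS) + list(ring_offsets(2))
    while queue:
        i = queue.popleft()
        h, v = int(coords[i][0]), int(coords[i][1])
        # collect assigned points near i in lattice space
        offs, pos = [], []
        for dh, dv in fit_offsets:
            j = coord_of.get((h + dh, v + dv))
            if j is not None:
                offs.append((dh, dv))
                pos.append(points[j])
        if len(offs) < 3:
            continue
        offs = np.asarray(offs, dtype=float)
        pos = np.asarray(pos)
        # affine model: position ~ c + B @ (dh, dv)
        A = np.column_stack([np.ones(len(offs)), offs])
        sol, *_ = np.linalg.lstsq(A, pos, rcond=None)
        c, B = sol[0], sol[1:]  # B: (2, 3)
        for dh, dv in NEIGHBOR_OFFSETS:
            key = (h + dh, v + dv)
            if key in coord_of:
                continue
            pred = c + np.array([dh, dv], dtype=float) @ B
            step = float(np.linalg.norm(np.array([dh, dv], dtype=float) @ B))
            if step <= 0:
                continue
            dist, j = tree.query(pred)
            if dist > match_tol * step or assigned[j]:
                continue
            coords[j] = key
            assigned[j] = True
            coord_of[key] = j
            queue.append(j)

    return ColumnGrid(ids=ids, positions=points, coords=coords, assigned=assigned)


def _bootstrap_hexagon(points, tree, seed, coords, assigned, local_pitch,
                       base=(0, 0)) -> None:
    """Label the six lattice neighbours of ``seed`` from estimated generators."""
    u, v, w, step = _local_generators(points, tree, seed)
    # offset labels: u is the (1,1) diagonal; the second generator is the
    # vertical (0,2) when it sits within 90° of u, otherwise the (-1,1)
    # diagonal with the vertical as their sum.
    if np.linalg.norm(u - v) <= np.linalg.norm(u + v):
        labels = [(u, (1, 1)), (v, (0, 2)), (w, (1, -1))]
    else:
        labels = [(u, (1, 1)), (v, (-1, 1)), (w, (0, 2))]
    h0, v0 = base
    n_hit = 0
    for vec, (dh, dv) in labels:
        for sgn in (+1, -1):
            pred = points[seed] + sgn * vec
            dist, j = tree.query(pred)
            if dist < 0.35 * np.linalg.norm(vec) and not assigned[j] and j != seed:
                coords[j] = (h0 + sgn * dh, v0 + sgn * dv)
                assigned[j] = True
                n_hit += 1
    if n_hit < 3:
        raise LatticeAssignmentError(
            "seed neighbourhood could not be labelled; choose an interior seed"
        )


def ring_offsets(ring: int) -> list[tuple[int, int]]:
    """Lattice offsets exactly ``ring`` steps from the origin, in angular order."""
    if ring == 0:
        return [(0, 0)]
    out = []
    for h in range(-ring, ring + 1):
        for v in range(-2 * ring, 2 * ring + 1):
            if (h + v) % 2 != 0:
                continue
            q, r = h, (v - h) // 2
            s = -q - r
            if max(abs(q), abs(r), abs(s)) == ring:
                out.append((h, v))
    # angular order in the regular-hex embedding
    out.sort(key=lambda hv: np.arctan2(hv[1] * 0.5, hv[0] * np.sqrt(3) / 2))
    return out


def reference_neighborhood(
    grid: ColumnGrid, centre: tuple[int, int], rings: int = 2
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Coordinates of the home column and its first ``rings`` rings.

    With ``rings=2`` this is the 19-point reference set (home + 6 + 12) used
    for the regular-grid mapping.  Returns ``(present, missing)``, both in a
    deterministic order (home first, then by ring and angle).

    Raises ``KeyError`` if ``centre`` is not an assigned coordinate.
    """
    centre = (int(centre[0]), int(centre[1]))
    if centre not in grid.coord_index:
        raise KeyError(f"centre {centre} not in grid")
    present, missing = [], []
    for ring in range(rings + 1):
        for dh, dv in ring_offsets(ring):
            c = (centre[0] + dh, centre[1] + dv)
            (present if c in grid.coord_index else missing).append(c)
    return present, missing


def find_landmarks(grid: ColumnGrid, equator_markers: Iterable[int]) -> ColumnGrid:
    """Locate the equator row and central meridian, setting the grid flags.

    ``equator_markers`` are point ids of the equatorial marker band (the
    columns whose lamina cartridges carry extra photoreceptors, or the
    chirality-flip band in the eye).  The equator is a single row chosen from
    that band: the middle row, with ties between the two middle rows broken
    toward the row that intersects the central meridian.  The central meridian
    is the ``h`` column that best splits the assigned points into equal halves.
    """
    marker_ids = set(int(i) for i in equator_markers)
    if not marker_ids:
        raise ValueError("equator_markers must be non-empty")
    id_to_row = {int(pid): i for i, pid in enumerate(grid.ids)}
    rows = sorted({int(grid.coords[id_to_row[m]][1]) for m in marker_ids
                   if m in id_to_row and grid.assigned[id_to_row[m]]})
    if not rows:
        raise ValueError("no assigned marker points")
    if rows[-1] - rows[0] != len(rows) - 1:
        raise ValueError("equator markers span non-adjacent rows")

    hs = grid.coords[grid.assigned, 0]
    candidates = np.unique(hs)
    imbalance = [abs(int(np.sum(hs < h0)) - int(np.sum(hs > h0))) for h0 in candidates]
    best = candidates[int(np.argmin(imbalance))]
    # deterministic tie-break: smallest |h|, then smallest h
    min_imb = min(imbalance)
    tied = [h0 for h0, im in zip(candidates, imbalance) if im == min_imb]
    best = sorted(tied, key=lambda h0: (abs(int(h0)), int(h0)))[0]

    if len(rows) % 2 == 1:
        v0 = rows[len(rows) // 2]
    else:
        middle = rows[len(rows) // 2 - 1: len(rows) // 2 + 1]
        # the meridian column has fixed h parity; exactly one of two adjacent
        # rows contains sites of that parity (h + v even)
        inter = [v for v in middle if (int(best) + v) % 2 == 0]
        v0 = inter[0] if inter else middle[0]

    grid.central_meridian = grid.assigned & (grid.coords[:, 0] == best)
    grid.equator_row = grid.assigned & (grid.coords[:, 1] == v0)
    return grid


def regular_positions(
    coords: Sequence[tuple[int, int]], pitch: float = 1.0, kind: str = "hexagonal"
) -> np.ndarray:
    """Embed lattice coordinates in a regular 2D reference grid.

    ``hexagonal``: nearest-neighbour distance = ``pitch`` in all six directions
    (x = h·√3/2·pitch, y = v·pitch/2) — the eye-style reference grid.
    ``square``: the 45°-tilted square grid used for medulla-style display
    (x = h·pitch/2, y = v·pitch/2).
    """
    c = np.asarray(list(coords), dtype=float)
    if kind == "hexagonal":
        return np.column_stack([c[:, 0] * (np.sqrt(3) / 2) * pitch,
                                c[:, 1] * 0.5 * pitch])
    if kind == "square":
        return np.column_stack([c[:, 0] * 0.5 * pitch, c[:, 1] * 0.5 * pitch])
    raise ValueError(f"unknown reference grid kind: {kind!r}")


def local_flatten(
    grid: ColumnGrid,
    neighborhood: Sequence[int],
    extra_points: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project a neighbourhood (plus extra points) onto its local PCA plane.

    The plane is perpendicular to the third principal axis of the
    neighbourhood positions.  The in-plane axes are rotated (and reflected if
    needed) so that the image of the lattice ``+v`` axis points along +y and
    the image of ``+h`` has a positive x component, making the output
    orientation deterministic.

    Parameters
    ----------
    neighborhood : sequence of row indices into ``grid``
    extra_points : (m, 3) array, optional
        Additional points (e.g. PD head/tail) projected onto the same plane.

    Returns
    -------
    (n, 2) and (m, 2) arrays of in-plane coordinates.
    """
    idx = np.asarray(list(neighborhood), dtype=int)
    if len(idx) < 3:
        raise ValueError("need at least 3 points to define a plane")
    pos = grid.positions[idx]
    centre = pos.mean(axis=0)
    u, s, vt = np.linalg.svd(pos - centre, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("neighbourhood is collinear; no plane defined")
    e1, e2 = vt[0], vt[1]
    xy = np.column_stack([(pos - centre) @ e1, (pos - centre) @ e2])

    # orient: fit (h, v) -> (x, y), then rotate +v image to +y
    hv = grid.coords[idx].astype(float)
    A = np.column_stack([np.ones(len(idx)), hv])
    sol, *_ = np.linalg.lstsq(A, xy, rcond=None)
    v_img = sol[2]  # d(x,y)/dv
    h_img = sol[1]
    nv = np.linalg.norm(v_img)
    if nv < 1e-12:
        raise ValueError("cannot orient plane: +v image degenerate")
    cosr, sinr = v_img[1] / nv, v_img[0] / nv
    R = np.array([[cosr, -sinr], [sinr, cosr]])  # rotates v_img to +y
    xy = xy @ R.T
    h_rot = R @ h_img
    if h_rot[0] < 0:
        xy[:, 0] = -xy[:, 0]
        flip = np.array([[-1.0, 0.0], [0.0, 1.0]])
        R = flip @ R
    if extra_points is not None and len(extra_points):
        ep = np.asarray(extra_points, dtype=float)
        exy = np.column_stack([(ep - centre) @ e1, (ep - centre) @ e2]) @ R.T
    else:
        exy = np.zeros((0, 2))
    return xy, exy


# ---------------------------------------------------------------------------
# lattice point group (used to compare assignments "up to global symmetry")
# ---------------------------------------------------------------------------

def lattice_symmetries() -> list[np.ndarray]:
    """The 12 point-group operations of the hex lattice on cube coordinates.

    Returned as 3x3 permutation-with-sign matrices acting on cube coords
    ``(x, y, z)`` with ``x + y + z = 0``.
    """
    rot = np.array([[0, 0, -1], [-1, 0, 0], [0, -1, 0]])  # 60° rotation
    refl = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0]])    # mirror
    ops = []
    m = np.eye(3, dtype=int)
    for _ in range(6):
        ops.append(m.copy())
        ops.append((m @ refl).copy())
        m = m @ rot
    return ops


def _coords_to_cube(coords: np.ndarray) -> np.ndarray:
    h = coords[:, 0]
    v = coords[:, 1]
    q = h
    r = (v - h) // 2
    return np.column_stack([q, -q - r, r])


def _cube_to_coords(cube: np.ndarray) -> np.ndarray:
    q = cube[:, 0]
    r = cube[:, 2]
    return np.column_stack([q, 2 * r + q])


def align_lattices(recovered: np.ndarray, truth: np.ndarray) -> float:
    """Best fraction of points whose recovered coords match the ground truth
    under some global lattice symmetry plus translation.

    Both inputs are (n, 2) integer ``(h, v)`` arrays for the *same* points in
    the same order.  Returns the matched fraction for the best of the 12
    point-group operations combined with the translation implied by the first
    point.
    """
    rec = _coords_to_cube(np.asarray(recovered, dtype=int))
    tru = _coords_to_cube(np.asarray(truth, dtype=int))
    best = 0.0
    for op in lattice_symmetries():
        mapped = rec @ op.T
        # translation candidates from a few anchor points (first, middle, last)
        for anchor in {0, len(rec) // 2, len(rec) - 1}:
            t = tru[anchor] - mapped[anchor]
            if t.sum() != 0:  # must stay on the x+y+z=0 plane
                continue
            frac = float(np.mean(np.all(mapped + t == tru, axis=1)))
            best = max(best, frac)
    return best
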