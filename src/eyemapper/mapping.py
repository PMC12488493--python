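"""Kernel-regression mapping between medulla, reference grid, and eye spaces.

The workhorse is a local-linear Gaussian kernel regression (LLKR): at each
query point a weighted least-squares line/plane is fit with Gaussian weights
and evaluated at the query.  The local-linear estimator reproduces affine
functions exactly and behaves well near boundaries.  Two bandwidth modes are
supported: a fixed bandwidth (used for interpolating dense PD fields) and an
adaptive nearest-neighbour bandwidth (used when mapping between two different
spaces, e.g. medulla → eye).  Bandwidths / neighbour counts are selected by
leave-one-out cross-validated squared error over a log-spaced ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hexgrid import ColumnGrid, local_flatten, reference_neighborhood, regular_positions
from .eye import OmmatidiaSet
from .skeleton import PDVector

__all__ = [
    "KernelModel",
    "llkr_fit_predict",
    "bandwidth_select",
    "EyeMap",
    "match_grids",
    "map_pd_to_grid",
    "map_pd_to_eye",
    "interpolate_pd_field",
    "TangentVectorField",
]

_RAD2DEG = 180.0 / np.pi


@dataclass
class KernelModel:
    """Gaussian-kernel local-linear regression configuration.

    mode='fixed': ``bandwidth`` is a scalar or per-dimension array.
    mode='adaptive_nn': ``k`` nearest training neighbours set the per-query
    bandwidth (distance to the k-th neighbour).
    """

    mode: str = "fixed"
    bandwidth: float | np.ndarray | None = None
    k: int | None = None
    ridge: float = 1e-8

    def __post_init__(self):
        if self.mode not in ("fixed", "adaptive_nn"):
            raise ValueError("mode must be 'fixed' or 'adaptive_nn'")
        if self.mode == "fixed" and self.bandwidth is not None:
            if np.any(np.asarray(self.bandwidth) <= 0):
                raise ValueError("bandwidth must be positive")
        if self.mode == "adaptive_nn" and self.k is not None and self.k < 3:
            raise ValueError("adaptive_nn needs k >= d + 2")


def _llkr_single(train_x, train_y, q, h, ridge):
    """Local-linear fit at one query point; returns the intercept."""
    dx = train_x - q                       # (n, d)
    u = dx / h
    w = np.exp(-0.5 * np.sum(u * u, axis=1))
    X = np.column_stack([np.ones(len(dx)), dx])
    WX = X * w[:, None]
    G = X.T @ WX                           # (d+1, d+1)
    b = WX.T @ train_y                     # (d+1, m)
    # plain solve when well conditioned (exact affine reproduction); ridge on
    # the slope block only for singular local designs (e.g. collinear weight)
    try:
        if np.linalg.cond(G) < 1e10:
            return np.linalg.solve(G, b)[0]
    except np.linalg.LinAlgError:
        pass
    warnings.warn("singular local design; ridge-regularized fit")
    lam = ridge * max(np.trace(G), 1e-300)
    reg = np.eye(G.shape[0]) * lam
    reg[0, 0] = 0.0
    sol = np.linalg.lstsq(G + reg, b, rcond=None)[0]
    return sol[0]


def llkr_fit_predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    query_x: np.ndarray,
    model: KernelModel,
) -> np.ndarray:
    """Local-linear Gaussian kernel regression predictions at ``query_x``.

    ``train_y`` may be vector-valued (n, m); components are fit jointly
    (same weights, shared normal matrix).  Returns (q, m) or (q,) matching
    the dimensionality of ``train_y``.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    if train_x.shape[0] == 1 and train_x.shape[1] > 1 and np.ndim(train_x) == 2:
        pass
    if np.asarray(train_x).ndim == 1:
        train_x = np.asarray(train_x, dtype=float)[:, None]
    query_x = np.asarray(query_x, dtype=float)
    scalar_query = query_x.ndim == 1 and train_x.shape[1] == len(query_x)
    q = np.atleast_2d(query_x) if query_x.ndim > 1 else (
        query_x[None, :] if scalar_query else query_x[:, None]
    )
    y = np.asarray(train_y, dtype=float)
    scalar_y = y.ndim == 1
    Y = y[:, None] if scalar_y else y
    n, d = train_x.shape
    if n < d + 2:
        raise ValueError(f"need at least d+2={d + 2} training points, got {n}")
    if not (np.all(np.isfinite(train_x)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite training data")

    if model.mode == "fixed":
        if model.bandwidth is None:
            raise ValueError("fixed mode requires a bandwidth")
        h = np.broadcast_to(np.asarray(model.bandwidth, dtype=float), (d,))
        hs = [h] * len(q)
    else:
        k = model.k
        if k is None:
            raise ValueError("adaptive_nn mode requires k")
        k = min(k, n - 1)
        from scipy.spatial import cKDTree

        tree = cKDTree(train_x)
        dists, _ = tree.query(q, k=min(k + 1, n))
        hk = np.maximum(dists[:, -1], 1e-12)
        hs = [np.full(d, hh) for hh in hk]

    out = np.empty((len(q), Y.shape[1]))
    for i, qq in enumerate(q):
        out[i] = _llkr_single(train_x, Y, qq, hs[i], model.ridge)
    if scalar_y:
        out = out[:, 0]
    if scalar_query:
        return out[0]
    return out


def _loo_cv_error(train_x, train_y, model: KernelModel) -> float:
    n = len(train_x)
    errs = np.empty(n)
    mask = np.ones(n, dtype=bool)
    Y = train_y if train_y.ndim > 1 else train_y[:, None]
    for i in range(n):
        mask[i] = False
        try:
            pred = llkr_fit_predict(train_x[mask], Y[mask], train_x[i], model)
        except ValueError:
            mask[i] = True
            return np.inf
        errs[i] = float(np.sum((pred - Y[i]) ** 2))
        mask[i] = True
    return float(np.mean(errs))


def bandwidth_select(
    train_x: np.ndarray,
    train_y: np.ndarray,
    model: KernelModel | None = None,
    n_candidates: int = 25,
) -> float | int:
    """Select the bandwidth (or neighbour count) by leave-one-out CV.

    For fixed mode the ladder is log-spaced from half the median
    nearest-neighbour spacing to four times the data diameter; for
    adaptive_nn it sweeps k from d+2 to n−1.  Deterministic given data;
    ties (within 1e-12 relative) resolve toward the larger bandwidth, the
    smoother and numerically safer choice.
    """
    train_x = np.asarray(train_x, dtype=float)
    if train_x.ndim == 1:
        train_x = train_x[:, None]
    train_y = np.asarray(train_y, dtype=float)
    n, d = train_x.shape
    if n < 10:
        raise ValueError("need at least 10 points for bandwidth selection")
    span = train_x.max(axis=0) - train_x.min(axis=0)
    if np.all(span <= 0):
        raise ValueError("degenerate (constant) training inputs")
    model = model or KernelModel(mode="fixed")

    if model.mode == "adaptive_nn":
        ks = np.arange(d + 2, n)
        errors = [
            _loo_cv_error(train_x, train_y, KernelModel("adaptive_nn", k=int(k),
                                                        ridge=model.ridge))
            for k in ks
        ]
        errors = np.asarray(errors)
        best = errors.min()
        scale = float(np.mean(np.square(train_y))) + 1e-300
        ok = errors <= best * (1 + 1e-9) + 1e-10 * scale
        return int(ks[np.flatnonzero(ok)[-1]])

    from scipy.spatial import cKDTree

    nn = cKDTree(train_x).query(train_x, k=2)[0][:, 1]
    lo = 0.5 * float(np.median(nn[nn > 0])) if np.any(nn > 0) else 1e-3
    hi = 4.0 * float(np.linalg.norm(span))
    ladder = np.geomspace(max(lo, 1e-12), hi, n_candidates)
    errors = np.array([
        _loo_cv_error(train_x, train_y, KernelModel("fixed", bandwidth=float(b),
                                                    ridge=model.ridge))
        for b in ladder
    ])
    best = errors.min()
    scale = float(np.mean(np.square(train_y))) + 1e-300
    ok = errors <= best * (1 + 1e-9) + 1e-10 * scale
    return float(ladder[np.flatnonzero(ok)[-1]])


# ---------------------------------------------------------------------------
# eye map: medulla columns <-> ommatidia directions
# ---------------------------------------------------------------------------

@dataclass
class EyeMap:
    """One-to-one pairing between medulla columns and ommatidia.

    ``pairs`` maps column id -> ommatidium id.  Coordinates are aligned at
    the (equator ∩ central meridian) origin of each set, with the optic-chiasm
    mirroring applied to the medulla ``h`` axis.  ``auxiliary`` holds one ring
    of extrapolated support points beyond the matched boundary, keyed by eye
    lattice coordinate, each with an extrapolated direction and column
    position used to stabilize boundary regressions.
    """

    pairs: dict[int, int]
    unmatched_columns: set[int]
    unmatched_ommatidia: set[int]
    column_origin: tuple[int, int]
    omm_origin: tuple[int, int]
    mirror_h: bool
    auxiliary: dict[tuple[int, int], dict] = field(default_factory=dict)

    def column_coord_to_eye(self, coord: tuple[int, int]) -> tuple[int, int]:
        """Medulla lattice coordinate -> aligned eye lattice coordinate."""
        h = coord[0] - self.column_origin[0]
        v = coord[1] - self.column_origin[1]
        if self.mirror_h:
            h = -h
        return (h + self.omm_origin[0], v + self.omm_origin[1])


def _grid_origin(coords: np.ndarray, equator: np.ndarray, meridian: np.ndarray):
    both = equator & meridian
    if both.any():
        i = int(np.flatnonzero(both)[0])
        return int(coords[i][0]), int(coords[i][1])
    if not equator.any() or not meridian.any():
        raise ValueError("grid landmarks (equator, central meridian) missing")
    h0 = int(coords[meridian][0][0])
    v0 = int(coords[equator][0][1])
    return h0, v0


def match_grids(medulla: ColumnGrid, omm: OmmatidiaSet) -> EyeMap:
    """Pair medulla columns with ommatidia by shared lattice coordinates.

    Origins are aligned at each set's (equator ∩ central meridian), the
    chiasm mirroring is applied when ``medulla.mirrored_h``, and identical
    coordinates are paired breadth-first from the origin outward.  Columns
    flagged ``no_inner_photoreceptor`` are excluded.  Coordinates present in
    only one set are reported unmatched.  One ring of auxiliary points is
    extrapolated beyond the matched boundary by local affine fits.
    """
    col_origin = _grid_origin(medulla.coords, medulla.equator_row,
                              medulla.central_meridian)
    omm_origin = _grid_origin(omm.coords, omm.equator_row, omm.central_meridian)
    mirror = bool(medulla.mirrored_h)

    emap = EyeMap(pairs={}, unmatched_columns=set(), unmatched_ommatidia=set(),
                  column_origin=col_origin, omm_origin=omm_origin, mirror_h=mirror)

    omm_index = omm.coord_index
    matched_omm = set()
    # BFS order: matched centre-outward (sorted by lattice ring from origin)
    order = []
    for i in range(len(medulla)):
        if not medulla.assigned[i] or medulla.no_inner_photoreceptor[i]:
            if medulla.assigned[i]:
                emap.unmatched_columns.add(int(medulla.ids[i]))
            continue
        eye_c = emap.column_coord_to_eye(tuple(medulla.coords[i]))
        dq = eye_c[0] - omm_origin[0]
        dr = ((eye_c[1] - omm_origin[1]) - dq) // 2
        ring = max(abs(dq), abs(dr), abs(-dq - dr))
        order.append((ring, int(medulla.ids[i]), i, eye_c))
    order.sort()
    for _, cid, i, eye_c in order:
        j = omm_index.get(eye_c)
        if j is None or j in matched_omm:
            emap.unmatched_columns.add(cid)
            continue
        emap.pairs[cid] = int(omm.ids[j])
        matched_omm.add(j)
    for j in range(len(omm)):
        if omm.assigned[j] and j not in matched_omm:
            emap.unmatched_ommatidia.add(int(omm.ids[j]))

    _add_auxiliary_ring(emap, medulla, omm, matched_omm)
    return emap


def _add_auxiliary_ring(emap: EyeMap, medulla: ColumnGrid, omm: OmmatidiaSet,
                        matched_omm: set[int]) -> None:
    """Extrapolate one ring of support points beyond the matched boundary."""
    from .hexgrid import NEIGHBOR_OFFSETS

    matched_eye_coords = {tuple(omm.coords[j]) for j in matched_omm}
    candidates = set()
    for (h, v) in matched_eye_coords:
        for dh, dv in NEIGHBOR_OFFSETS:
            c = (h + dh, v + dv)
            if c not in matched_eye_coords:
                candidates.add(c)
    if not candidates:
        return
    # affine fits over matched points near each candidate
    coords_arr = np.array(sorted(matched_eye_coords))
    omm_dirs = {tuple(omm.coords[j]): omm.directions[j] for j in matched_omm}
    col_pos = {}
    id_row = {int(medulla.ids[i]): i for i in range(len(medulla))}
    omm_id_row = {int(omm.ids[j]): j for j in range(len(omm))}
    for cid, oid in emap.pairs.items():
        col_pos[tuple(omm.coords[omm_id_row[oid]])] = medulla.positions[id_row[cid]]

    for c in sorted(candidates):
        d2 = np.abs(coords_arr[:, 0] - c[0]) + np.abs(coords_arr[:, 1] - c[1])
        near = coords_arr[d2 <= 4]
        if len(near) < 4:
            continue
        A = np.column_stack([np.ones(len(near)), near])
        q = np.array([1.0, c[0], c[1]])
        D = np.array([omm_dirs[tuple(cc)] for cc in near])
        sol, *_ = np.linalg.lstsq(A, D, rcond=None)
        direction = q @ sol
        direction = direction / np.linalg.norm(direction)
        P = np.array([col_pos[tuple(cc)] for cc in near])
        solp, *_ = np.linalg.lstsq(A, P, rcond=None)
        emap.auxiliary[c] = {"direction": direction, "column_position": q @ solp}


# ---------------------------------------------------------------------------
# PD mapping
# ---------------------------------------------------------------------------

def _default_adaptive(train_x, train_y, model: KernelModel | None) -> KernelModel:
    if model is not None:
        return model
    try:
        k = bandwidth_select(train_x, train_y, KernelModel("adaptive_nn"))
    except ValueError:
        k = min(9, len(train_x) - 1)
    return KernelModel("adaptive_nn", k=int(k))


def map_pd_to_grid(
    pd: PDVector,
    grid: ColumnGrid,
    model: KernelModel | None = None,
    reference: str = "hexagonal",
) -> PDVector:
    """Map a PD vector from medulla µm space into the regular reference grid.

    The home column's 19-point neighbourhood (home + 6 + 12) is locally
    flattened by PCA; head, tail and centre of the PD are regressed from the
    flattened medulla plane onto the regular reference grid (unit pitch,
    centred on the home column, so mapped positions are directly comparable
    across cells).  ``length_grid_units`` is recomputed from the mapped
    head/tail.
    """
    if pd.home_coord is None:
        raise ValueError("PD has no home coordinate")
    present, missing = reference_neighborhood(grid, pd.home_coord, rings=2)
    ring1 = set()
    from .hexgrid import NEIGHBOR_OFFSETS

    for dh, dv in NEIGHBOR_OFFSETS:
        ring1.add((pd.home_coord[0] + dh, pd.home_coord[1] + dv))
    if any(c in ring1 for c in missing):
        raise ValueError(
            "home column lacks a complete first ring (boundary neuron excluded)"
        )
    idx = [grid.coord_index[c] for c in present]
    extras = np.stack([pd.head, pd.tail, pd.centre])
    xy, exy = local_flatten(grid, idx, extras)
    rel_coords = [(c[0] - pd.home_coord[0], c[1] - pd.home_coord[1]) for c in present]
    ref = regular_positions(rel_coords, pitch=1.0, kind=reference)
    model = _default_adaptive(xy, ref, model)
    mapped = llkr_fit_predict(xy, ref, exy, model)
    head2, tail2, centre2 = mapped
    vec = head2 - tail2
    length = float(np.linalg.norm(vec))
    direction = np.array([vec[0], vec[1], 0.0]) / max(length, 1e-300)
    out = PDVector(
        centre=np.array([centre2[0], centre2[1], 0.0]),
        direction=direction,
        length=pd.length,
        width=pd.width,
        length_grid_units=length,
        cell_id=pd.cell_id,
        home_coord=pd.home_coord,
    )
    return out


def map_pd_to_eye(
    pd: PDVector,
    eyemap: EyeMap,
    grid: ColumnGrid,
    omm: OmmatidiaSet,
    model: KernelModel | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Map a medulla PD into eye coordinates as a tangent vector.

    Head, tail and centre are regressed from the locally flattened 2D medulla
    neighbourhood onto the unit sphere of ommatidia directions (componentwise,
    then radially re-projected).  Returns ``(base_direction, tangent_vector,
    magnitude_deg)`` where the tangent vector has norm equal to the
    head-to-tail great-circle span in degrees and is orthogonal to the base.
    """
    if pd.home_coord is None:
        raise ValueError("PD has no home coordinate")
    id_row = {int(grid.ids[i]): i for i in range(len(grid))}
    home_idx = grid.coord_index.get(tuple(pd.home_coord))
    if home_idx is None:
        raise ValueError("home column not in grid")
    home_cid = int(grid.ids[home_idx])
    if home_cid not in eyemap.pairs:
        raise ValueError("home column unmatched in the eye map")
    omm_row = {int(omm.ids[j]): j for j in range(len(omm))}
    base = omm.directions[omm_row[eyemap.pairs[home_cid]]]

    present, _ = reference_neighborhood(grid, pd.home_coord, rings=2)
    rows, targets = [], []
    for c in present:
        i = grid.coord_index[c]
        cid = int(grid.ids[i])
        if cid in eyemap.pairs:
            rows.append(i)
            targets.append(omm.directions[omm_row[eyemap.pairs[cid]]])
    # auxiliary support beyond the boundary
    aux_pos, aux_dir = [], []
    for c in present:
        eye_c = eyemap.column_coord_to_eye(c)
        if eye_c in eyemap.auxiliary and grid.coord_index.get(c) is None:
            aux_pos.append(eyemap.auxiliary[eye_c]["column_position"])
            aux_dir.append(eyemap.auxiliary[eye_c]["direction"])
    if len(rows) < 5:
        raise ValueError("too few matched neighbours for eye mapping")
    extras = np.stack([pd.head, pd.tail, pd.centre] + aux_pos) if aux_pos else \
        np.stack([pd.head, pd.tail, pd.centre])
    xy, exy = local_flatten(grid, rows, extras)
    train_x = np.vstack([xy, exy[3:]]) if aux_pos else xy
    train_y = np.vstack([np.asarray(targets)] + ([np.asarray(aux_dir)] if aux_dir else []))
    model = _default_adaptive(train_x, train_y, model)
    mapped = llkr_fit_predict(train_x, train_y, exy[:3], model)
    head = mapped[0] / np.linalg.norm(mapped[0])
    tail = mapped[1] / np.linalg.norm(mapped[1])
    span = float(np.degrees(np.arccos(np.clip(head @ tail, -1.0, 1.0))))
    w = head - tail
    t = w - (w @ base) * base
    tn = np.linalg.norm(t)
    if tn < 1e-12:
        return base, np.zeros(3), span
    return base, (t / tn) * span, span


@dataclass
class TangentVectorField:
    """One tangent vector per viewing direction (PD fields, flow fields)."""

    base: np.ndarray     # (n, 3) unit directions
    vectors: np.ndarray  # (n, 3) tangent vectors (v · d = 0)
    ids: np.ndarray | None = None
    magnitude_kind: str = "pd_span_deg"  # or "flow_speed"

    def __post_init__(self):
        self.base = np.asarray(self.base, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.ids is None:
            self.ids = np.arange(len(self.base))

    def __len__(self) -> int:
        return len(self.base)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def tangency_error(self) -> float:
        return float(np.max(np.abs(np.sum(self.vectors * self.base, axis=1))))


def interpolate_pd_field(
    sparse: TangentVectorField,
    omm: OmmatidiaSet,
    model: KernelModel | None = None,
    display_rescale: float | None = None,
) -> TangentVectorField:
    """Interpolate a sparse tangent field to every ommatidium direction.

    Componentwise fixed-bandwidth LLKR over the 3D base directions, followed
    by re-projection onto the tangent plane at each query direction.  The
    default bandwidth is 2.5× the median neighbour chord of the ommatidia set.
    ``display_rescale`` multiplies vector lengths for display only.
    """
    if len(sparse) == 0:
        raise ValueError("empty sparse field")
    if len(sparse) < 10:
        raise ValueError("need at least 10 sparse vectors")
    if model is None:
        from scipy.spatial import cKDTree

        nn = cKDTree(omm.directions).query(omm.directions, k=2)[0][:, 1]
        model = KernelModel("fixed", bandwidth=2.5 * float(np.median(nn)))
    pred = llkr_fit_predict(sparse.base, sparse.vectors, omm.directions, model)
    d = omm.directions
    pred = pred - np.sum(pred * d, axis=1, keepdims=True) * d
    if display_rescale is not None:
        pred = pred * display_rescale
    return TangentVectorField(base=d.copy(), vectors=pred, ids=omm.ids.copy(),
                              magnitude_kind=sparse.magnitude_kind)
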