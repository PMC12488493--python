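"""Ideal optic-flow fields and self-motion axis search.

Flow fields are expressed as the motion *perceived* by the animal.  For a
rotation about the unit axis ω the perceived flow at viewing direction d is
``F(d) = d × ω``; for a translation along the unit axis t under the
equal-distance assumption it is the vector rejection ``F(d) = (t·d)d − t``
(the scene streams opposite to self-motion).  The self-motion axis a PD field
senses best is found by exhaustive grid search over a quasi-uniform Fibonacci
sampling of candidate axes, minimizing the average angular difference between
the candidate's flow field and the PD field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import TangentVectorField

__all__ = [
    "MotionAxis",
    "AxisSearchResult",
    "rotation_flow",
    "translation_flow",
    "angular_difference",
    "sample_axes",
    "optimal_axis",
    "cardinal_axes",
]


@dataclass
class MotionAxis:
    axis: np.ndarray  # unit 3-vector
    mode: str         # 'rotation' | 'translation'

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n < 1e-12:
            raise ValueError("zero motion axis")
        self.axis = self.axis / n
        if self.mode not in ("rotation", "translation"):
            raise ValueError("mode must be 'rotation' or 'translation'")


@dataclass
class AxisSearchResult:
    best: MotionAxis
    error_deg: float                  # summary angular difference at the optimum
    error_map: np.ndarray             # per-candidate summary error, degrees
    axes: np.ndarray                  # (n_axes, 3) candidates
    n_axes: int = 0
    resolution_deg: float = np.nan
    statistic: str = "mean"

    def __post_init__(self):
        self.n_axes = len(self.axes)


def _check_directions(directions: np.ndarray) -> np.ndarray:
    d = np.asarray(directions, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("directions must be (n, 3)")
    return d


def _dirs_of(omm) -> np.ndarray:
    """Accept an OmmatidiaSet, a TangentVectorField, or a plain (n, 3) array."""
    if isinstance(omm, TangentVectorField):
        return _check_directions(omm.base)
    if hasattr(omm, "directions"):
        return _check_directions(omm.directions)
    return _check_directions(np.asarray(omm, dtype=float))


def rotation_flow(omm, omega: np.ndarray) -> TangentVectorField:
    """Perceived flow for self-rotation about ``omega``: F(d) = d × ω."""
    d = _dirs_of(omm)
    omega = np.asarray(omega, dtype=float)
    if np.linalg.norm(omega) < 1e-12:
        raise ValueError("zero rotation axis")
    vec = np.cross(d, omega)
    ids = getattr(omm, "ids", None)
    return TangentVectorField(base=d.copy(), vectors=vec, ids=None if ids is None else ids.copy(),
                              magnitude_kind="flow_speed")


def translation_flow(omm, t: np.ndarray) -> TangentVectorField:
    """Perceived flow for self-translation along ``t``: F(d) = (t·d)d − t.

    Assumes all scene objects are at equal (unit) distance.
    """
    d = _dirs_of(omm)
    t = np.asarray(t, dtype=float)
    if np.linalg.norm(t) < 1e-12:
        raise ValueError("zero translation axis")
    vec = (d @ t)[:, None] * d - t
    ids = getattr(omm, "ids", None)
    return TangentVectorField(base=d.copy(), vectors=vec, ids=None if ids is None else ids.copy(),
                              magnitude_kind="flow_speed")


def angular_difference(
    a: TangentVectorField, b: TangentVectorField, return_mask: bool = False
):
    """Per-direction unsigned angle between two tangent fields, degrees.

    Both fields must share base directions.  Directions where either vector
    has zero length are excluded (reported via the mask when requested).
    """
    if a.base.shape != b.base.shape or not np.allclose(a.base, b.base, atol=1e-9):
        raise ValueError("fields must share base directions")
    va, vb, d = a.vectors, b.vectors, a.base
    cross = np.cross(va, vb)
    sin_term = np.sum(cross * d, axis=1)
    cos_term = np.sum(va * vb, axis=1)
    ang = np.abs(np.degrees(np.arctan2(sin_term, cos_term)))
    ok = (np.linalg.norm(va, axis=1) > 1e-12) & (np.linalg.norm(vb, axis=1) > 1e-12)
    ang = np.where(ok, ang, np.nan)
    if return_mask:
        return ang, ok
    return ang


def sample_axes(n: int) -> np.ndarray:
    """Deterministic quasi-uniform axes on the unit sphere (Fibonacci lattice)."""
    if n < 2:
        raise ValueError("need at least 2 axes")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def axis_resolution_deg(axes: np.ndarray) -> float:
    """Mean nearest-neighbour angle of an axis set, degrees."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(axes).query(axes, k=2)
    chord = d[:, 1]
    return float(np.degrees(2 * np.arcsin(np.clip(chord / 2, 0, 1))).mean())


def optimal_axis(
    pd: TangentVectorField,
    mode: str,
    n_axes: int = 10356,
    statistic: str = "mean",
    chunk: int = 512,
) -> AxisSearchResult:
    """Grid-search the self-motion axis whose ideal flow best matches ``pd``.

    Evaluates the summary (mean or median) angular difference between the PD
    field and the flow field of every candidate axis, returning the argmin
    with the full error map.
    """
    if mode not in ("rotation", "translation"):
        raise ValueError("mode must be 'rotation' or 'translation'")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if len(pd) == 0:
        raise ValueError("empty PD field")
    axes = sample_axes(n_axes)
    d = pd.base                      # (n, 3)
    v = pd.vectors
    vnorm = np.linalg.norm(v, axis=1)
    keep = vnorm > 1e-12
    d, v = d[keep], v[keep]

    errs = np.empty(len(axes))
    summarize = np.nanmean if statistic == "mean" else np.nanmedian
    for s in range(0, len(axes), chunk):
        A = axes[s:s + chunk]        # (m, 3)
        if mode == "rotation":
            F = np.cross(d[None, :, :], A[:, None, :])      # (m, n, 3)
        else:
            dot = d @ A.T                                   # (n, m)
            F = dot.T[:, :, None] * d[None, :, :] - A[:, None, :]
        sin_term = np.sum(np.cross(v[None, :, :], F) * d[None, :, :], axis=2)
        cos_term = np.sum(v[None, :, :] * F, axis=2)
        ang = np.abs(np.degrees(np.arctan2(sin_term, cos_term)))
        fnorm = np.linalg.norm(F, axis=2)
        ang = np.where(fnorm > 1e-12, ang, np.nan)
        errs[s:s + chunk] = summarize(ang, axis=1)
    best_i = int(np.argmin(errs))
    return AxisSearchResult(
        best=MotionAxis(axes[best_i], mode),
        error_deg=float(errs[best_i]),
        error_map=errs,
        axes=axes,
        resolution_deg=axis_resolution_deg(axes) if n_axes <= 20000 else np.nan,
        statistic=statistic,
    )


def cardinal_axes() -> dict[str, MotionAxis]:
    """Cardinal self-motion axes in the eye frame (x front, z up).

    yaw: rotation about +z; roll: rotation about the frontal midline;
    pitch: rotation about the lateral axis; thrust: forward translation;
    reverse_thrust: backward; side_slip: lateral; lift: dorsal.
    """
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    return {
        "yaw": MotionAxis(z, "rotation"),
        "roll": MotionAxis(x, "rotation"),
        "pitch": MotionAxis(y, "rotation"),
        "thrust": MotionAxis(x, "translation"),
        "reverse_thrust": MotionAxis(-x, "translation"),
        "side_slip": MotionAxis(y, "translation"),
        "lift": MotionAxis(z, "translation"),
    }
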