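"""Arena-stimulus geometry and local PD estimation from tuning curves.

The electrophysiology display is a cylindrical LED arena around the fly:
240° of azimuth, ~50° of elevation, each pixel subtending ~1.25° at the eye.
This module derives stimulus kinematics (temporal frequency, angular speed,
window size, duration) from printed arena parameters, maps arena pixels into
the compound-eye reference frame (arena rotation, then head orientation), and
computes local preferred directions from directional tuning curves by vector
summation of baseline-subtracted responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaGeometry",
    "StimulusSpec",
    "TuningCurve",
    "StimulusKinematics",
    "stimulus_kinematics",
    "arena_to_eye",
    "local_pd_from_tuning",
]


@dataclass
class ArenaGeometry:
    """Cylindrical LED arena parameters (angles in degrees)."""

    pixel_pitch_deg: float = 1.25
    azimuth_span_deg: float = 240.0
    elevation_span_deg: float = 50.0
    arena_rotation_deg: float = 0.0            # 0 or 30 in the experiments
    head_orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # yaw,pitch,roll

    def __post_init__(self):
        if self.pixel_pitch_deg <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.azimuth_span_deg <= 0 or self.elevation_span_deg <= 0:
            raise ValueError("arena spans must be positive")


@dataclass
class StimulusSpec:
    """Square-wave grating or moving-edge stimulus."""

    kind: str = "grating"          # 'grating' | 'edge'
    on_pixels: int = 7
    off_pixels: int = 7
    step_ms: float = 40.0
    window_pixels: int = 21
    n_cycles: int = 3

    def __post_init__(self):
        if self.step_ms <= 0:
            raise ValueError("step duration must be positive")
        if self.on_pixels < 1 or self.off_pixels < 1 or self.window_pixels < 1:
            raise ValueError("pixel counts must be >= 1")


@dataclass
class StimulusKinematics:
    temporal_frequency_hz: float
    angular_speed_deg_s: float
    window_diameter_deg: float
    duration_s: float
    spatial_period_deg: float


def stimulus_kinematics(spec: StimulusSpec, arena: ArenaGeometry) -> StimulusKinematics:
    """Closed-form stimulus kinematics from arena pixel parameters.

    spatial period = (on + off) pixels; temporal frequency = 1 / (period ×
    step); angular speed = pixel pitch / step; window diameter =
    window pixels × pitch; duration = cycles × period × step.
    """
    period_px = spec.on_pixels + spec.off_pixels
    step_s = spec.step_ms / 1000.0
    return StimulusKinematics(
        temporal_frequency_hz=1.0 / (period_px * step_s),
        angular_speed_deg_s=arena.pixel_pitch_deg / step_s,
        window_diameter_deg=spec.window_pixels * arena.pixel_pitch_deg,
        duration_s=spec.n_cycles * period_px * step_s,
        spatial_period_deg=period_px * arena.pixel_pitch_deg,
    )


def _rot(axis: str, deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def arena_to_eye(pixel_coords: np.ndarray, arena: ArenaGeometry) -> np.ndarray:
    """Map arena pixel indices to unit directions in the eye frame.

    ``pixel_coords`` is (n, 2) of (column, row) indices relative to the arena
    centre pixel (column 0, row 0 = frontal midline at the equator).  Pixels
    sit on a cylinder: columns step azimuth by the pixel pitch; rows step
    physical height by the matching cylinder-surface pixel size, so apparent
    elevation compresses away from the equator (the cylinder–sphere
    distortion).  The chain is pixel → cylinder point → lab direction →
    arena rotation (about the lateral axis) → head orientation
    (yaw → pitch → roll) → unit vector in the eye frame (x front, z up).
    """
    px = np.atleast_2d(np.asarray(pixel_coords, dtype=float))
    az = px[:, 0] * arena.pixel_pitch_deg
    if np.any(np.abs(az) > arena.azimuth_span_deg / 2 + 1e-9):
        raise ValueError("pixel outside arena azimuth span")
    row_height = 2.0 * np.tan(np.deg2rad(arena.pixel_pitch_deg) / 2.0)
    zc = px[:, 1] * row_height
    if np.any(np.abs(np.degrees(np.arctan(zc)))
              > arena.elevation_span_deg / 2 + arena.pixel_pitch_deg):
        raise ValueError("pixel outside arena elevation span")
    az_r = np.deg2rad(az)
    dirs = np.column_stack([np.cos(az_r), np.sin(az_r), zc])
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)

    R = _rot("y", arena.arena_rotation_deg)
    yaw, pitch, roll = arena.head_orientation
    Rhead = _rot("z", yaw) @ _rot("y", pitch) @ _rot("x", roll)
    out = dirs @ R.T @ Rhead.T
    if np.ndim(pixel_coords) == 1:
        return out[0]
    return out


@dataclass
class TuningCurve:
    """Directional tuning: mean spike rates at a set of motion directions."""

    directions_deg: np.ndarray  # strictly increasing within [0, 360)
    rates_hz: np.ndarray        # mean rate per direction (trial-averaged)
    baseline_hz: float = 0.0
    cell: str | int | None = None
    location: tuple[float, float] | None = None  # (azimuth, elevation) deg

    def __post_init__(self):
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        self.rates_hz = np.asarray(self.rates_hz, dtype=float)
        d = self.directions_deg
        if len(d) < 2:
            raise ValueError("need at least 2 directions")
        if np.any(np.diff(d) <= 0) or d[0] < 0 or d[-1] >= 360:
            raise ValueError("directions must be strictly increasing in [0, 360)")
        if not np.all(np.isfinite(self.rates_hz)):
            raise ValueError("rates must be finite")


def local_pd_from_tuning(curve: TuningCurve) -> tuple[float, float]:
    """Local PD as the vector sum of baseline-subtracted responses.

    Each direction contributes ``r_i · (cos θ_i, sin θ_i)`` with ``r_i`` the
    baseline-subtracted rate; suppression below baseline (negative ``r_i``)
    contributes an opposite-pointing vector.  Returns ``(pd_deg, length)``;
    ``pd_deg`` is NaN when the sum has no usable magnitude (all-zero or
    perfectly uniform responses), which is the explicit 'PD undefined' signal.
    """
    r = curve.rates_hz - curve.baseline_hz
    th = np.deg2rad(curve.directions_deg)
    vx = float(np.sum(r * np.cos(th)))
    vy = float(np.sum(r * np.sin(th)))
    length = float(np.hypot(vx, vy))
    scale = float(np.sum(np.abs(r)))
    if scale == 0.0 or length < 1e-9 * max(scale, 1.0):
        return float("nan"), length
    pd = float(np.degrees(np.arctan2(vy, vx))) % 360.0
    if pd >= 360.0:  # guard the -0.0 wrap
        pd = 0.0
    return pd, length
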