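"""Mollweide (equal-area) and Mercator (conformal) map projections.

Angles at the interface are degrees; longitude = azimuth, latitude =
elevation.  The Mollweide auxiliary angle solves ``2θ + sin 2θ = π sin(lat)``
by Newton iteration to 1e-10 (with the closed form at the poles).  Both
projections provide exact inverses away from their singular sets.
"""

from __future__ import annotations

import numpy as np

__all__ = ["project", "unproject", "mollweide", "mollweide_inverse",
           "mercator", "mercator_inverse"]

_SQRT2 = np.sqrt(2.0)


def _mollweide_theta(lat_rad: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Solve 2θ + sin 2θ = π sin(lat) for θ (Newton, pole-safe)."""
    lat_rad = np.asarray(lat_rad, dtype=float)
    theta = lat_rad.copy()
    target = np.pi * np.sin(lat_rad)
    at_pole = np.isclose(np.abs(lat_rad), np.pi / 2)
    for _ in range(100):
        f = 2 * theta + np.sin(2 * theta) - target
        df = 2 + 2 * np.cos(2 * theta)
        step = np.where(at_pole | (np.abs(df) < 1e-14), 0.0, f / np.maximum(df, 1e-14))
        theta = theta - step
        if np.all(np.abs(step) < tol):
            break
    theta = np.where(at_pole, np.sign(lat_rad) * np.pi / 2, theta)
    return theta


def mollweide(lon_deg, lat_deg, radius: float = 1.0):
    """Equal-area Mollweide projection. Returns (x, y)."""
    lon = np.deg2rad(np.asarray(lon_deg, dtype=float))
    lat = np.deg2rad(np.asarray(lat_deg, dtype=float))
    theta = _mollweide_theta(lat)
    x = radius * (2 * _SQRT2 / np.pi) * lon * np.cos(theta)
    y = radius * _SQRT2 * np.sin(theta)
    return x, y


def mollweide_inverse(x, y, radius: float = 1.0):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.arcsin(np.clip(y / (radius * _SQRT2), -1.0, 1.0))
    lat = np.arcsin(np.clip((2 * theta + np.sin(2 * theta)) / np.pi, -1.0, 1.0))
    cos_t = np.cos(theta)
    lon = np.where(
        np.abs(cos_t) < 1e-14, 0.0, np.pi * x / (2 * radius * _SQRT2 * np.maximum(cos_t, 1e-14))
    )
    return np.rad2deg(lon), np.rad2deg(lat)


def mercator(lon_deg, lat_deg, radius: float = 1.0):
    """Conformal Mercator projection; singular at |lat| = 90°."""
    lat = np.asarray(lat_deg, dtype=float)
    if np.any(np.abs(lat) >= 90.0):
        raise ValueError("Mercator projection is singular at |elevation| = 90°")
    lon_r = np.deg2rad(np.asarray(lon_deg, dtype=float))
    lat_r = np.deg2rad(lat)
    x = radius * lon_r
    y = radius * np.log(np.tan(np.pi / 4 + lat_r / 2))
    return x, y


def mercator_inverse(x, y, radius: float = 1.0):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = x / radius
    lat = 2 * np.arctan(np.exp(y / radius)) - np.pi / 2
    return np.rad2deg(lon), np.rad2deg(lat)


def project(lon_deg, lat_deg, kind: str, radius: float = 1.0):
    """Dispatch to 'mollweide' or 'mercator'."""
    if kind == "mollweide":
        return mollweide(lon_deg, lat_deg, radius)
    if kind == "mercator":
        return mercator(lon_deg, lat_deg, radius)
    raise ValueError(f"unknown projection kind: {kind!r}")


def unproject(x, y, kind: str, radius: float = 1.0):
    if kind == "mollweide":
        return mollweide_inverse(x, y, radius)
    if kind == "mercator":
        return mercator_inverse(x, y, radius)
    raise ValueError(f"unknown projection kind: {kind!r}")
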