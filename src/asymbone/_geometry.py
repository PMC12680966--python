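"""Planar polygon primitives shared by the sectioning, landmark and CSG stages.

Polygons are (n, 2) float arrays of vertices, implicitly closed (the last
vertex connects back to the first) and oriented counter-clockwise unless
stated otherwise.  Area moments are computed with the Green's-theorem
polygon formulas; single-valued radial sampling assumes the polygon is
star-shaped with respect to the query centre.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import NonStarShapeError

__all__ = [
    "signed_area",
    "ensure_ccw",
    "perimeter",
    "polygon_centroid",
    "polygon_raw_moments",
    "resample_arclength",
    "is_simple_polygon",
    "polygon_contains",
    "ray_intersections",
]


def signed_area(poly: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise orientation."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def ensure_ccw(poly: np.ndarray) -> np.ndarray:
    """Return the polygon with counter-clockwise orientation."""
    if signed_area(poly) < 0:
        return poly[::-1].copy()
    return np.asarray(poly, dtype=float)


def perimeter(poly: np.ndarray) -> float:
    d = np.roll(poly, -1, axis=0) - poly
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def polygon_raw_moments(poly: np.ndarray) -> dict:
    """Area, first and second moments about the coordinate origin.

    Returns a dict with keys ``A`` (area), ``Sx``/``Sy`` (first moments
    ∫x dA, ∫y dA), ``Ixx`` (∫y² dA), ``Iyy`` (∫x² dA) and ``Ixy`` (∫xy dA).
    The polygon must be counter-clockwise for positive area.
    """
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    sx = np.sum((x + xn) * cross) / 6.0
    sy = np.sum((y + yn) * cross) / 6.0
    ixx = np.sum((y * y + y * yn + yn * yn) * cross) / 12.0
    iyy = np.sum((x * x + x * xn + xn * xn) * cross) / 12.0
    ixy = np.sum((x * yn + 2.0 * x * y + 2.0 * xn * yn + xn * y) * cross) / 24.0
    return {"A": float(a), "Sx": float(sx), "Sy": float(sy),
            "Ixx": float(ixx), "Iyy": float(iyy), "Ixy": float(ixy)}


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    m = polygon_raw_moments(poly)
    return np.array([m["Sx"] / m["A"], m["Sy"] / m["A"]])


def resample_arclength(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` vertices equally spaced in arc length.

    The first output vertex coincides with the first input vertex; the output
    is open (implicitly closed) like the input.
    """
    poly = np.asarray(poly, dtype=float)
    closed = np.vstack([poly, poly[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    target = np.linspace(0.0, total, n, endpoint=False)
    xs = np.interp(target, s, closed[:, 0])
    ys = np.interp(target, s, closed[:, 1])
    return np.column_stack([xs, ys])


def is_simple_polygon(poly: np.ndarray) -> bool:
    """True if the closed polyline does not self-intersect."""
    return _ShapelyPolygon(poly).is_valid


def polygon_contains(outer: np.ndarray, inner: np.ndarray) -> bool:
    """True if ``inner`` lies strictly inside ``outer`` (no boundary contact)."""
    return _ShapelyPolygon(outer).contains(_ShapelyPolygon(inner))


def _unwrapped_vertex_angles(poly: np.ndarray, center: np.ndarray,
                             level_percent=None):
    """Monotone unwrapped polar angles of the vertices about ``center``.

    Raises :class:`NonStarShapeError` if the angular sequence backtracks,
    i.e. the polygon is not star-shaped (single-valued in r(θ)) about the
    centre, or if the total winding is not one full turn.
    """
    v = poly - center
    phi = np.arctan2(v[:, 1], v[:, 0])
    d = np.diff(phi)
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    closing = (phi[0] - phi[-1] + np.pi) % (2.0 * np.pi) - np.pi
    if np.any(d < -1e-9) or closing < -1e-9:
        bad = int(np.argmin(np.append(d, closing)))
        raise NonStarShapeError(
            "contour is not star-shaped about the section centre "
            f"(angular backtrack near vertex {bad})",
            level_percent=level_percent,
            angle_deg=float(np.degrees(phi[min(bad, len(phi) - 1)])),
        )
    total = float(np.sum(d) + closing)
    if abs(total - 2.0 * np.pi) > 1e-6:
        raise NonStarShapeError(
            f"contour winds {total / (2 * np.pi):.3f} turns about the centre "
            "(expected exactly one)", level_percent=level_percent)
    return phi[0], np.concatenate([[phi[0]], phi[0] + np.cumsum(np.append(d, closing))])


def ray_intersections(poly: np.ndarray, center: np.ndarray, angles: np.ndarray,
                      level_percent=None) -> np.ndarray:
    """Intersection of rays from ``center`` at ``angles`` (radians) with a
    star-shaped closed polygon.

    Exactly one crossing per ray is guaranteed by the star-shape check; the
    bracketing edge of each ray is located by a binary search on the
    unwrapped vertex angles, then intersected exactly.  Returns (k, 2) points.
    """
    poly = np.asarray(poly, dtype=float)
    center = np.asarray(center, dtype=float)
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    n = len(poly)
    phi0, phiu = _unwrapped_vertex_angles(poly, center, level_percent)
    # map query angles into [phi0, phi0 + 2π)
    tau = (angles - phi0) % (2.0 * np.pi) + phi0
    idx = np.searchsorted(phiu, tau, side="right") - 1
    idx = np.clip(idx, 0, n - 1)
    p1 = poly[idx]
    p2 = poly[(idx + 1) % n]
    w = p2 - p1
    b = p1 - center
    u = np.column_stack([np.cos(tau), np.sin(tau)])
    denom = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
    # degenerate bracketing edge (duplicate vertices): fall back to vertex
    safe = np.abs(denom) > 1e-300
    t = np.empty(len(tau))
    t[safe] = (b[safe, 0] * w[safe, 1] - b[safe, 1] * w[safe, 0]) / denom[safe]
    t[~safe] = np.hypot(b[~safe, 0], b[~safe, 1])
    if np.any(t <= 0):
        raise NonStarShapeError(
            "ray-contour intersection behind the section centre",
            level_percent=level_percent)
    return center + t[:, None] * u
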