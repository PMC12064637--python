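"""Independent oracles used by the test suite.

These deliberately avoid the package's shapely-based geometry routines:
volumes come from vertical-column integration on a grid, containment from
point-in-projected-triangle counting, and segment intersections from
per-pair shapely calls (the implementation uses its own vectorized math).
"""

from __future__ import annotations

import numpy as np

# distinct x/y grid offsets avoid columns landing exactly on mesh edges or
# face-triangulation diagonals (phantoms use integer-ish coordinates)
_JITTER_X = 0.2137
_JITTER_Y = 0.3719


def _column_thickness(mesh, pts_xy: np.ndarray) -> np.ndarray:
    """Total z-thickness of the solid above/below each xy point."""
    tris = mesh.triangles
    thick = np.zeros(len(pts_xy))
    for t in tris:
        (ax, ay, az), (bx, by, bz), (cx, cy, cz) = t
        det = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
        if abs(det) < 1e-12:
            continue
        px = pts_xy[:, 0] - ax
        py = pts_xy[:, 1] - ay
        u = (px * (cy - ay) - py * (cx - ax)) / det
        v = (py * (bx - ax) - px * (by - ay)) / det
        inside = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not inside.any():
            continue
        z = az + u[inside] * (bz - az) + v[inside] * (cz - az)
        thick[inside] += np.sign(det) * z
    return thick


def column_grid(mesh, pitch: float):
    lo, hi = mesh.bounds
    xs = np.arange(lo[0] + _JITTER_X * pitch, hi[0] + pitch, pitch)
    ys = np.arange(lo[1] + _JITTER_Y * pitch, hi[1] + pitch, pitch)
    X, Y = np.meshgrid(xs, ys)
    return np.column_stack([X.ravel(), Y.ravel()])


def column_volume(mesh, pitch: float = 0.5) -> float:
    """Volume by summing per-column solid thickness over a regular xy grid."""
    pts = column_grid(mesh, pitch)
    return float(_column_thickness(mesh, pts).sum() * pitch * pitch)


def column_volume_in_polygon(mesh, polygon_xy: np.ndarray, pitch: float = 0.5) -> float:
    """Volume restricted to columns whose center falls inside a 2D polygon."""
    from matplotlib.path import Path as MplPath

    pts = column_grid(mesh, pitch)
    mask = MplPath(polygon_xy).contains_points(pts)
    pts = pts[mask]
    if not len(pts):
        return 0.0
    return float(_column_thickness(mesh, pts).sum() * pitch * pitch)


def vertical_hit_oracle(mesh, pts_xy: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Vertical line hits the solid iff the column thickness is positive or a
    nearby probe says so (guards exact-boundary samples)."""
    pts = np.atleast_2d(pts_xy)
    hit = _column_thickness(mesh, pts) > eps
    return hit


def brute_force_chain_crossings(points: np.ndarray):
    """All-pairs crossing detection between non-adjacent chain segments,
    one shapely call per pair."""
    from shapely.geometry import LineString

    pts = np.asarray(points, dtype=float)
    n = len(pts) - 1
    out = []
    for i in range(n):
        for j in range(i + 2, n):
            a = LineString([pts[i], pts[i + 1]])
            b = LineString([pts[j], pts[j + 1]])
            inter = a.intersection(b)
            if inter.is_empty:
                continue
            if inter.geom_type == "Point":
                out.append((inter.x, inter.y))
            else:  # collinear overlap
                out.append(None)
    return out


def silhouette_contains_oracle(mesh, pts_xy: np.ndarray) -> np.ndarray:
    """Containment in the footprint via a shapely union of projected
    triangles, built locally (not the package's cached silhouette)."""
    from shapely.geometry import Point, Polygon
    from shapely.ops import unary_union

    tris = mesh.triangles[:, :, :2]
    polys = []
    for t in tris:
        p = Polygon(t)
        if p.area > 1e-12:
            polys.append(p if p.is_valid else p.buffer(0))
    sil = unary_union(polys)
    return np.array([sil.distance(Point(p)) < 1e-9 for p in np.atleast_2d(pts_xy)])
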