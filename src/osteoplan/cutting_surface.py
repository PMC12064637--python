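"""Cutting path -> extruded, oriented cutting surface, and mesh splitting.

The optimization variable is an open polygonal chain of n+1 xy-points.  Its
extrusion along z gives n vertical rectangular facets (one saw cut each).
Facet normals follow three orientation cases driven by the polar-angle gaps
of consecutive points about the tumor centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geom2d
from ._geom2d import MeshPrismCache, SplitError, cross2
from .mesh_core import SurgicalCase, TriangleMesh

DEGENERATE_SEGMENT = 1e-6  # mm; shorter segments collapse to redundant planes


@dataclass
class CuttingPath:
    """Ordered list of n+1 (x, y) points, i.e. 2(n+1) scalars."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 2:
            raise ValueError("a cutting path needs at least 2 points")

    @property
    def n_segments(self) -> int:
        return len(self.points) - 1

    def as_flat(self) -> np.ndarray:
        return self.points.ravel().copy()

    @classmethod
    def from_flat(cls, raw: np.ndarray) -> "CuttingPath":
        raw = np.asarray(raw, dtype=float).ravel()
        if raw.size % 2:
            raise ValueError("flat coordinates must have even length")
        return cls(raw.reshape(-1, 2))


@dataclass
class PlanarFacet:
    """One vertical rectangular cutting facet (a single saw cut)."""

    a: np.ndarray  # (x, y) of first endpoint
    b: np.ndarray  # (x, y) of second endpoint
    z_min: float
    z_max: float
    normal: np.ndarray  # unit 3-vector, z-component 0
    degenerate: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)

    def plane(self) -> dict:
        """Point + normal description of the facet's infinite plane."""
        m = self.midpoint
        return {
            "point": [float(m[0]), float(m[1]), 0.5 * (self.z_min + self.z_max)],
            "normal": [float(self.normal[0]), float(self.normal[1]), 0.0],
        }


@dataclass
class CuttingSurface:
    """Ordered facets from extruding a chain along z."""

    facets: list[PlanarFacet]
    source_path: CuttingPath
    z_range: tuple[float, float]
    oriented: bool = False
    invalid_reason: str | None = field(default=None)

    @property
    def n_facets(self) -> int:
        return len(self.facets)

    def segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(f.a, f.b) for f in self.facets]


def order_points_polar(
    points: np.ndarray, center=(0.0, 0.0), branch_angle: float = 0.0
) -> CuttingPath:
    """Order points by ascending polar angle about ``center``.

    The circular order is opened at ``branch_angle``: the chain starts with
    the first point counter-clockwise after that direction, so the open gap
    of the chain contains it.  For a planning case the branch points from the
    bone footprint toward the tumor centroid - the sector where the tumor
    protrudes and no cut is needed.  Ties are broken by radius ascending,
    then x, then y, giving a total deterministic order.  A point coinciding
    with the center has no polar angle and raises ValueError.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    ctr = np.asarray(center, dtype=float).reshape(2)
    rel = pts - ctr
    r = np.hypot(rel[:, 0], rel[:, 1])
    if (r < 1e-12).any():
        raise ValueError("a path point coincides with the centroid")
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]) - branch_angle, 2.0 * np.pi)
    order = np.lexsort((pts[:, 1], pts[:, 0], r, theta))
    return CuttingPath(pts[order])


def build_surface(path: CuttingPath, z_extent) -> CuttingSurface:
    """Extrude each chain segment into a vertical facet spanning ``z_extent``.

    The default normal is the left-hand perpendicular; call
    :func:`orient_facets` to apply the centroid-based orientation rules.
    """
    z_min, z_max = float(z_extent[0]), float(z_extent[1])
    if not z_min < z_max:
        raise ValueError("z_extent must satisfy z_min < z_max")
    facets = []
    pts = path.points
    for i in range(path.n_segments):
        a, b = pts[i], pts[i + 1]
        d = b - a
        L = np.linalg.norm(d)
        if L < DEGENERATE_SEGMENT:
            facets.append(
                PlanarFacet(a.copy(), b.copy(), z_min, z_max, np.zeros(3), degenerate=True)
            )
            continue
        n2 = np.array([-d[1], d[0]]) / L
        facets.append(
            PlanarFacet(a.copy(), b.copy(), z_min, z_max, np.array([n2[0], n2[1], 0.0]))
        )
    return CuttingSurface(facets=facets, source_path=path, z_range=(z_min, z_max))


def z_extent_for(bone: TriangleMesh, overshoot: float = 0.05) -> tuple[float, float]:
    """Bone z-extent inflated by 5% each side so the extrusion always covers it."""
    z0, z1 = bone.bounds[0, 2], bone.bounds[1, 2]
    pad = max((z1 - z0) * overshoot, 1.0)
    return (float(z0 - pad), float(z1 + pad))


def _point_in_triangle(p, a, b, c, tol=1e-12) -> bool:
    d1 = cross2(b - a, p - a)
    d2 = cross2(c - b, p - b)
    d3 = cross2(a - c, p - c)
    neg = (d1 < -tol) or (d2 < -tol) or (d3 < -tol)
    pos = (d1 > tol) or (d2 > tol) or (d3 > tol)
    return not (neg and pos)


def orient_facets(surface: CuttingSurface, centroid=(0.0, 0.0)) -> CuttingSurface:
    """Assign facet normal directions relative to the tumor centroid.

    With points in polar order, consecutive angle gaps determine three cases:
    all gaps < pi -> every normal points away from the centroid; one gap > pi
    on an ending facet -> only that facet's normal points away (the others
    face the centroid); one gap > pi on an intermediate facet -> that facet
    faces the centroid iff the next path point falls inside the triangle of
    the pair and the centroid, all other normals point away.  The operation
    recomputes every normal from scratch, so it is idempotent.
    """
    ctr = np.asarray(centroid, dtype=float).reshape(2)
    pts = surface.source_path.points
    rel = pts - ctr
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * np.pi)
    gaps = np.mod(np.diff(theta), 2.0 * np.pi)
    reflex = np.nonzero(gaps > np.pi)[0]

    n = surface.n_facets
    if len(reflex) > 1:
        surface.invalid_reason = "multi-reflex-gap"
        return surface
    surface.invalid_reason = None

    toward = np.zeros(n, dtype=bool)  # facets whose normal must face the centroid
    if len(reflex) == 1:
        j = int(reflex[0])
        if j == 0 or j == n - 1:
            # ending facet: only it points away, the rest face the centroid
            toward[:] = True
            toward[j] = False
        else:
            nxt = pts[j + 2]
            if _point_in_triangle(nxt, pts[j], pts[j + 1], ctr):
                toward[j] = True

    for i, facet in enumerate(surface.facets):
        if facet.degenerate:
            continue
        d = facet.b - facet.a
        L = np.linalg.norm(d)
        n2 = np.array([-d[1], d[0]]) / L
        away = facet.midpoint - ctr
        s = float(n2 @ away)
        if s == 0.0:
            s = 1.0  # midpoint exactly at centroid direction: keep left normal
        n2 = n2 if s > 0 else -n2
        if toward[i]:
            n2 = -n2
        facet.normal = np.array([n2[0], n2[1], 0.0])
    surface.oriented = True
    return surface


def surface_from_raw(
    raw: np.ndarray, centroid=(0.0, 0.0), z_extent=(-1.0, 1.0)
) -> CuttingSurface:
    """Polar-order raw coordinates, build and orient the surface."""
    path = order_points_polar(np.asarray(raw, dtype=float).reshape(-1, 2), centroid)
    surf = build_surface(path, z_extent)
    return orient_facets(surf, centroid)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _active_segments(surface: CuttingSurface) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(f.a, f.b) for f in surface.facets if not f.degenerate]


def split_with_surface(
    mesh: TriangleMesh,
    surface: CuttingSurface,
    centroid=(0.0, 0.0, 0.0),
    cache: MeshPrismCache | None = None,
) -> TriangleMesh:
    """Resected (centroid-side) part of ``mesh`` cut by the surface.

    Raises :class:`SplitError` with reason ``no-contact`` when the surface
    misses the mesh footprint entirely and ``null-split`` when no component
    contains the centroid; callers translate these into penalties.
    """
    if cache is None:
        cache = MeshPrismCache.build(mesh)
    ctr = np.asarray(centroid, dtype=float).ravel()[:2]
    region = _geom2d.split_region(cache.sil, surface.source_path.points, ctr)
    return _geom2d.split_mesh_prism(mesh, cache, region, _active_segments(surface))


def split_both(
    mesh: TriangleMesh,
    surface: CuttingSurface,
    centroid=(0.0, 0.0, 0.0),
    cache: MeshPrismCache | None = None,
) -> tuple[TriangleMesh, TriangleMesh]:
    """(resected, remainder) parts; their volumes sum to the input volume."""
    if cache is None:
        cache = MeshPrismCache.build(mesh)
    ctr = np.asarray(centroid, dtype=float).ravel()[:2]
    region = _geom2d.split_region(cache.sil, surface.source_path.points, ctr)
    rest = _geom2d.complement_region(cache.sil, region)
    segs = _active_segments(surface)
    resected = _geom2d.split_mesh_prism(mesh, cache, region, segs)
    remainder = _geom2d.split_mesh_prism(mesh, cache, rest, segs)
    return resected, remainder


def resected_volume(
    mesh: TriangleMesh,
    surface: CuttingSurface,
    centroid=(0.0, 0.0, 0.0),
    cache: MeshPrismCache | None = None,
) -> float:
    """Volume of the centroid-side part without building the split mesh."""
    if cache is None:
        cache = MeshPrismCache.build(mesh)
    ctr = np.asarray(centroid, dtype=float).ravel()[:2]
    region = _geom2d.split_region(cache.sil, surface.source_path.points, ctr)
    return _geom2d.prism_volume(cache, region)


def resected_volumes(case: SurgicalCase, path: CuttingPath) -> tuple[float, float]:
    """(vol_B_cut, vol_T_left) for an already-validated path on a case.

    The margin-expanded tumor is the one split, so vol_T_left = 0 certifies
    clearance of the safety margin.  Split failures propagate as
    :class:`SplitError` for the objective's penalty path.
    """
    from .objective import CaseGeometry  # local import to avoid a cycle

    geom = CaseGeometry.for_case(case)
    path = order_points_polar(path.points, (0.0, 0.0), geom.branch_angle)
    region = _geom2d.split_region(geom.scene_sil, path.points, (0.0, 0.0))
    vol_b = _geom2d.prism_volume(geom.bone_cache, region)
    vol_t_cut = _geom2d.prism_volume(geom.tumor_cache, region)
    vol_t_left = max(geom.vol_tumor_total - vol_t_cut, 0.0)
    return vol_b, vol_t_left


def path_to_csv(path: CuttingPath) -> str:
    lines = ["x_mm,y_mm"]
    for x, y in path.points:
        lines.append(f"{x:.9g},{y:.9g}")
    return "\n".join(lines) + "\n"


def path_from_csv(text: str) -> CuttingPath:
    rows = [r for r in text.strip().splitlines() if r and not r.lower().startswith("x")]
    pts = np.asarray([[float(v) for v in r.split(",")[:2]] for r in rows])
    return CuttingPath(pts)


def facet_planes_json(surface: CuttingSurface) -> list[dict]:
    out = []
    for i, f in enumerate(surface.facets):
        entry = {"index": i, "degenerate": bool(f.degenerate)}
        if not f.degenerate:
            entry.update(f.plane())
            entry["endpoints"] = [f.a.tolist(), f.b.tolist()]
            entry["z_range"] = [f.z_min, f.z_max]
        out.append(entry)
    return out
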