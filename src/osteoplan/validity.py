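"""Detection of invalid cutting-path configurations.

Two classes of configuration are rejected and penalized by the objective:
facets whose plane crosses the bone but whose finite extent misses it, and
chain self-intersections whose vertical line passes through bone or tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

from ._geom2d import cross2, silhouette
from .cutting_surface import CuttingPath, CuttingSurface
from .mesh_core import TriangleMesh, vertical_lines_hit

__all__ = [
    "ValidityReport",
    "check_all_facets_cut",
    "find_self_intersections",
    "find_collinear_overlaps",
    "self_intersection_hits_mesh",
    "validate_configuration",
]


@dataclass
class ValidityReport:
    all_facets_cut: bool
    facet_miss_indices: list[int]
    self_intersections: list[tuple[float, float]]
    self_intersection_hits_mesh: bool
    degenerate_overlap: bool = False
    is_valid: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_valid = (
            self.all_facets_cut
            and not self.self_intersection_hits_mesh
            and not self.degenerate_overlap
        )

    def to_dict(self) -> dict:
        return {
            "all_facets_cut": self.all_facets_cut,
            "facet_miss_indices": list(map(int, self.facet_miss_indices)),
            "self_intersections": [[float(x), float(y)] for x, y in self.self_intersections],
            "self_intersection_hits_mesh": self.self_intersection_hits_mesh,
            "degenerate_overlap": self.degenerate_overlap,
            "is_valid": self.is_valid,
        }


def check_all_facets_cut(
    bone: TriangleMesh, surface: CuttingSurface, bone_sil=None
) -> tuple[bool, list[int]]:
    """Does every facet's finite extent actually intersect the bone?

    Each facet's infinite vertical plane is intersected with the bone; the
    contour is expressed in the facet's own in-plane axis and the facet
    misses iff no contour interval overlaps the facet's [0, L] span.  The
    contour range equals the bone footprint cut by the plane's trace line, so
    the test runs on the silhouette.  A plane that misses the bone entirely
    also counts as a miss.
    """
    sil = bone_sil if bone_sil is not None else silhouette(bone)
    minx, miny, maxx, maxy = sil.bounds
    reach = 2.0 * max(maxx - minx, maxy - miny) + 1.0
    misses: list[int] = []
    for i, facet in enumerate(surface.facets):
        if facet.degenerate:
            continue  # collapsed facet: redundant plane, exempt from the check
        a, b = facet.a, facet.b
        L = facet.length
        d = (b - a) / L
        trace = LineString([a - reach * d, b + reach * d]).intersection(sil)
        hit = False
        for g in getattr(trace, "geoms", [trace]):
            if g.is_empty or not isinstance(g, LineString):
                continue
            s0 = float((np.asarray(g.coords[0]) - a) @ d)
            s1 = float((np.asarray(g.coords[-1]) - a) @ d)
            lo, hi = sorted((s0, s1))
            if hi > 0.0 and lo < L:
                hit = True
                break
        if not hit:
            misses.append(i)
    return (len(misses) == 0, misses)


def _seg_intersection(p, q, r, s, tol=1e-12):
    """Intersection point of segments pq and rs, or None.

    Touching (endpoint on the other segment) counts; collinear overlap is
    reported separately and returns None here.
    """
    d1 = q - p
    d2 = s - r
    denom = cross2(d1, d2)
    diff = r - p
    if abs(denom) < tol:
        return None  # parallel (collinear overlap handled elsewhere)
    t = cross2(diff, d2) / denom
    u = cross2(diff, d1) / denom
    if -tol <= t <= 1 + tol and -tol <= u <= 1 + tol:
        return p + t * d1
    return None


def find_self_intersections(path: CuttingPath) -> list[tuple[float, float]]:
    """Transverse crossings between non-adjacent segments of the open chain."""
    pts = path.points
    n = len(pts) - 1
    out: list[tuple[float, float]] = []
    for i in range(n):
        for j in range(i + 2, n):
            pt = _seg_intersection(pts[i], pts[i + 1], pts[j], pts[j + 1])
            if pt is not None:
                out.append((float(pt[0]), float(pt[1])))
    return out


def find_collinear_overlaps(path: CuttingPath, tol: float = 1e-9) -> list[tuple[int, int]]:
    """Non-adjacent segment pairs that overlap collinearly (degenerate chains)."""
    pts = path.points
    n = len(pts) - 1
    out: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 2, n):
            p, q = pts[i], pts[i + 1]
            r, s = pts[j], pts[j + 1]
            d1, d2 = q - p, s - r
            if abs(cross2(d1, d2)) > tol or abs(cross2(d1, r - p)) > tol:
                continue
            L = np.linalg.norm(d1)
            if L < tol:
                continue
            u = d1 / L
            t0, t1 = 0.0, L
            t2, t3 = sorted((float((r - p) @ u), float((s - p) @ u)))
            if min(t1, t3) - max(t0, t2) > tol:
                out.append((i, j))
    return out


def self_intersection_hits_mesh(
    crossings: list[tuple[float, float]],
    bone: TriangleMesh,
    tumor: TriangleMesh,
) -> bool:
    """True iff any crossing's full vertical line intersects bone or tumor.

    Both z directions are tested since the extrusion spans the whole scene;
    any hit means the configuration must be penalized.
    """
    if not crossings:
        return False
    pts = np.asarray(crossings, dtype=float)
    return bool(vertical_lines_hit(bone, pts).any() or vertical_lines_hit(tumor, pts).any())


def validate_configuration(
    bone: TriangleMesh,
    tumor: TriangleMesh,
    surface: CuttingSurface,
    bone_sil=None,
) -> ValidityReport:
    ok, misses = check_all_facets_cut(bone, surface, bone_sil=bone_sil)
    crossings = find_self_intersections(surface.source_path)
    overlaps = find_collinear_overlaps(surface.source_path)
    hits = self_intersection_hits_mesh(crossings, bone, tumor)
    return ValidityReport(
        all_facets_cut=ok,
        facet_miss_indices=misses,
        self_intersections=crossings,
        self_intersection_hits_mesh=hits,
        degenerate_overlap=bool(overlaps),
    )
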