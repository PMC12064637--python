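"""Internal 2D/2.5D geometry engine.

Because every cutting facet is parallel to z, splitting a mesh with the
extruded chain reduces to 2D: the chain slits the mesh's xy-silhouette, the
resected region is the connected component containing the tumor centroid, and
the resected solid is the mesh restricted to that region's vertical prism.
Volumes over a prism are exact: only mesh triangles contribute z-flux, so
V = sum over triangles of the integral of z over (projection ∩ region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import (
    GeometryCollection,
    LineString,
    MultiPolygon,
    Point,
    Polygon,
    box,
)
from shapely.ops import unary_union

from .mesh_core import TriangleMesh

SLIT = 1e-9  # half-width of the slit cut along the chain (mm); volume error ~ SLIT * length


def cross2(a: np.ndarray, b: np.ndarray):
    """z-component of the cross product of 2D vectors (numpy 2 dropped this)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


class SplitError(RuntimeError):
    """Split produced no usable result; carries a reason code."""

    def __init__(self, reason: str, message: str = ""):
        super().__init__(message or reason)
        self.reason = reason


def _polygons(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, (MultiPolygon, GeometryCollection)):
        out = []
        for g in geom.geoms:
            out.extend(_polygons(g))
        return out
    return []


def silhouette(mesh: TriangleMesh, min_area: float = 1e-12) -> Polygon | MultiPolygon:
    """xy-footprint of the mesh: union of all projected triangles."""
    tri = mesh.triangles[:, :, :2]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    area2 = np.abs(cross2(b - a, c - a))
    keep = tri[area2 > min_area]
    polys = shapely.polygons(keep)
    polys = shapely.make_valid(polys)
    return unary_union(polys)


def chain_linestring(points: np.ndarray) -> LineString:
    return LineString(np.asarray(points, dtype=float))


def split_region(sil, chain_points: np.ndarray, origin_xy=(0.0, 0.0)):
    """Component of ``silhouette minus chain-slit`` containing ``origin_xy``.

    Returns a shapely polygon, or raises :class:`SplitError` with reason
    ``no-contact`` (chain never touches the footprint) or ``null-split``
    (no component contains the origin point).
    """
    line = chain_linestring(chain_points)
    if not line.intersects(sil):
        raise SplitError("no-contact", "cutting surface does not intersect mesh footprint")
    slit = line.buffer(SLIT, cap_style="flat")
    remainder = sil.difference(slit)
    origin = Point(origin_xy)
    for poly in _polygons(remainder):
        if poly.covers(origin):
            return poly
    raise SplitError("null-split", "no split component contains the centroid")


def complement_region(sil, region):
    """Silhouette area not in ``region`` (the remainder side of the split)."""
    return sil.difference(region)


# ---------------------------------------------------------------------------
# Prism-restricted volume
# ---------------------------------------------------------------------------

@dataclass
class MeshPrismCache:
    """Per-mesh precomputation reused across many region queries."""

    mesh: TriangleMesh
    tri_polys: np.ndarray  # shapely polygon per non-vertical triangle
    signs: np.ndarray  # sign of projected (shoelace) area
    full_terms: np.ndarray  # signed integral of z over each full projection
    plane_abc: np.ndarray  # per-triangle coefficients of z = a x + b y + c
    sil: object  # silhouette polygon

    @classmethod
    def build(cls, mesh: TriangleMesh) -> "MeshPrismCache":
        tri = mesh.triangles
        p2 = tri[:, :, :2]
        a, b, c = p2[:, 0], p2[:, 1], p2[:, 2]
        signed_area = 0.5 * cross2(b - a, c - a)
        keep = np.abs(signed_area) > 1e-12
        tri = tri[keep]
        p2 = p2[keep]
        signed_area = signed_area[keep]
        zmean = tri[:, :, 2].mean(axis=1)
        full_terms = signed_area * zmean

        # plane z = a x + b y + c through each triangle
        ones = np.ones((len(tri), 3, 1))
        M = np.concatenate([p2, ones], axis=2)
        abc = np.linalg.solve(M, tri[:, :, 2][..., None])[..., 0]

        polys = shapely.polygons(p2)
        return cls(
            mesh=mesh,
            tri_polys=polys,
            signs=np.sign(signed_area),
            full_terms=full_terms,
            plane_abc=abc,
            sil=silhouette(mesh),
        )

    def total_volume(self) -> float:
        return abs(float(self.full_terms.sum()))


def _linear_integral(geom, abc: np.ndarray) -> float:
    """Integral of (a x + b y + c) over a shapely area geometry."""
    total = 0.0
    for poly in _polygons(geom):
        A = poly.area
        if A <= 0:
            continue
        ctr = poly.centroid
        total += A * (abc[0] * ctr.x + abc[1] * ctr.y + abc[2])
    return total


def prism_volume(cache: MeshPrismCache, region) -> float:
    """Exact volume of the mesh part whose xy-projection lies in ``region``.

    Fully-contained triangles use precomputed integrals; boundary-crossing
    ones are clipped and integrated in a single vectorized pass.
    """
    shapely.prepare(region)
    inter = shapely.intersects(region, cache.tri_polys)
    within = shapely.contains_properly(region, cache.tri_polys)
    vol = float(cache.full_terms[within].sum())
    crossing = np.nonzero(inter & ~within)[0]
    if len(crossing):
        clipped = shapely.intersection(cache.tri_polys[crossing], region)
        parts, idx = shapely.get_parts(clipped, return_index=True)
        keep = shapely.get_type_id(parts) == 3  # polygons only
        parts, idx = parts[keep], idx[keep]
        areas = shapely.area(parts)
        pos = areas > 0
        if pos.any():
            parts, idx, areas = parts[pos], idx[pos], areas[pos]
            cents = shapely.centroid(parts)
            cx, cy = shapely.get_x(cents), shapely.get_y(cents)
            abc = cache.plane_abc[crossing[idx]]
            signs = cache.signs[crossing[idx]]
            vol += float(
                np.sum(signs * areas * (abc[:, 0] * cx + abc[:, 1] * cy + abc[:, 2]))
            )
    # sign convention: upward faces positive, so the sum is already the
    # enclosed volume for an outward-oriented mesh
    return abs(vol)


# ---------------------------------------------------------------------------
# Polygon triangulation (ear clipping, simple polygons without holes)
# ---------------------------------------------------------------------------

def ear_clip(coords: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple polygon given as (N, 2) CCW coordinates."""
    pts = np.asarray(coords, dtype=float)
    n = len(pts)
    if n < 3:
        return []
    idx = list(range(n))
    # enforce CCW
    area = 0.0
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    if area < 0:
        idx = idx[::-1]
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(idx)
        ear_found = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            if cross2(b - a, c - a) <= 1e-14:
                continue  # reflex or degenerate corner
            ok = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = pts[j]
                d1 = cross2(b - a, p - a)
                d2 = cross2(c - b, p - b)
                d3 = cross2(a - c, p - c)
                if d1 > -1e-14 and d2 > -1e-14 and d3 > -1e-14:
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                ear_found = True
                break
        if not ear_found:
            # numerically stuck: drop the most degenerate corner
            worst, wk = None, 0
            for k in range(m):
                i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
                cr = abs(cross2(pts[i1] - pts[i0], pts[i2] - pts[i0]))
                if worst is None or cr < worst:
                    worst, wk = cr, k
            idx.pop(wk)
    if len(idx) == 3:
        tris.append((idx[0], idx[1], idx[2]))
    return tris


def triangulate_polygon(poly: Polygon) -> list[np.ndarray]:
    """Triangles (each (3, 2)) covering a shapely polygon (holes unsupported)."""
    out: list[np.ndarray] = []
    for p in _polygons(poly):
        if p.area <= 0:
            continue
        ext = np.asarray(p.exterior.coords)[:-1]
        if len(p.interiors):
            # holes cannot arise from convex-triangle ∩ simply-connected
            # region clips; fall back to a small triangle grid approximation
            ext = np.asarray(p.convex_hull.exterior.coords)[:-1]
        for i0, i1, i2 in ear_clip(ext):
            out.append(np.array([ext[i0], ext[i1], ext[i2]]))
    return out


# ---------------------------------------------------------------------------
# Mesh cross-section with a vertical plane (for wall construction and the
# facet-cut validity check)
# ---------------------------------------------------------------------------

def vertical_plane_section(
    mesh: TriangleMesh, p0: np.ndarray, direction: np.ndarray
) -> list[np.ndarray]:
    """Closed loops of the mesh section by the vertical plane through ``p0``
    (xy point) with in-plane horizontal ``direction``.

    Returns loops as (K, 2) arrays of (s, z), s measured along ``direction``.
    """
    p0 = np.asarray(p0, dtype=float).reshape(2)
    d = np.asarray(direction, dtype=float).reshape(2)
    d = d / np.linalg.norm(d)
    normal = np.array([-d[1], d[0]])

    verts = mesh.vertices
    w = (verts[:, :2] - p0) @ normal
    w = np.where(w == 0.0, 1e-13, w)  # nudge vertices off the plane
    faces = mesh.faces
    wf = w[faces]
    crossing = ~((wf > 0).all(axis=1) | (wf < 0).all(axis=1))
    if not crossing.any():
        return []

    # intersection point on each crossing (undirected) edge, keyed by edge id
    edge_pts: dict[tuple[int, int], np.ndarray] = {}
    seg_edges: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for f in faces[crossing]:
        cuts = []
        for i, j in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if w[i] * w[j] < 0:
                key = (min(i, j), max(i, j))
                if key not in edge_pts:
                    t = w[i] / (w[i] - w[j])
                    pt3 = verts[i] + t * (verts[j] - verts[i])
                    edge_pts[key] = np.array([(pt3[:2] - p0) @ d, pt3[2]])
                cuts.append(key)
        if len(cuts) == 2:
            seg_edges.append((cuts[0], cuts[1]))

    # stitch segments into loops via shared edge keys
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in seg_edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    visited: set[tuple[int, int]] = set()
    loops: list[np.ndarray] = []
    for start in adj:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur, prev = start, None
        while True:
            nxt = None
            for cand in adj[cur]:
                if cand != prev and (cand not in visited or (cand == start and len(loop) > 2)):
                    nxt = cand
                    break
            if nxt is None or nxt == start:
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(np.array([edge_pts[k] for k in loop]))
    return loops


def section_polygon(mesh: TriangleMesh, p0, direction):
    """Section loops merged into a shapely area geometry in (s, z) plane."""
    loops = vertical_plane_section(mesh, p0, direction)
    polys = []
    for lp in loops:
        poly = Polygon(lp)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.area > 1e-12:
            polys.append(poly)
    if not polys:
        return Polygon()
    return unary_union(polys)


# ---------------------------------------------------------------------------
# Full mesh split: surface clipping + cut walls, returned as triangle soup of
# individually closed pieces
# ---------------------------------------------------------------------------

def _clip_vertical_triangle(tri3: np.ndarray, region) -> list[np.ndarray]:
    """Clip a (near-)vertical 3D triangle to a prism region via its projected
    segment; returns 3D triangles."""
    p2 = tri3[:, :2]
    # principal direction of the degenerate projection
    dmax, pair = -1.0, (0, 1)
    for i, j in ((0, 1), (1, 2), (0, 2)):
        dd = np.linalg.norm(p2[j] - p2[i])
        if dd > dmax:
            dmax, pair = dd, (i, j)
    if dmax < 1e-9:
        return []  # projects to a point: zero contribution either way
    a2, b2 = p2[pair[0]], p2[pair[1]]
    d = (b2 - a2) / dmax
    seg = LineString([a2, b2]).intersection(region)
    pieces = []
    geoms = getattr(seg, "geoms", [seg])
    for g in geoms:
        if isinstance(g, LineString) and g.length > 1e-9:
            s0 = (np.asarray(g.coords[0]) - a2) @ d
            s1 = (np.asarray(g.coords[-1]) - a2) @ d
            lo, hi = sorted((s0, s1))
            poly = [tri3[0], tri3[1], tri3[2]]
            # clip by s >= lo and s <= hi (convex clip in 3D)
            for nrm, off in (((d[0], d[1], 0.0), lo), ((-d[0], -d[1], 0.0), -hi)):
                nrm = np.asarray(nrm)
                new = []
                m = len(poly)
                for i in range(m):
                    cur, nxt = poly[i], poly[(i + 1) % m]
                    wc = (cur[:2] - a2) @ nrm[:2] - off
                    wn = (nxt[:2] - a2) @ nrm[:2] - off
                    if wc >= -1e-12:
                        new.append(cur)
                    if (wc < 0) != (wn < 0) and abs(wc - wn) > 1e-15:
                        t = wc / (wc - wn)
                        new.append(cur + t * (nxt - cur))
                poly = new
                if len(poly) < 3:
                    break
            for k in range(1, len(poly) - 1):
                pieces.append(np.array([poly[0], poly[k], poly[k + 1]]))
    return pieces


def clip_mesh_to_region(mesh: TriangleMesh, cache: MeshPrismCache, region) -> list[np.ndarray]:
    """Mesh surface triangles restricted to the vertical prism over ``region``.

    Returns a list of (3, 3) triangles preserving the original orientation.
    """
    shapely.prepare(region)
    tri_all = mesh.triangles
    p2 = tri_all[:, :, :2]
    a, b, c = p2[:, 0], p2[:, 1], p2[:, 2]
    signed_area = 0.5 * cross2(b - a, c - a)
    vertical = np.abs(signed_area) <= 1e-12

    out: list[np.ndarray] = []
    # non-vertical triangles via the cached shapely polygons
    nz_index = np.nonzero(~vertical)[0]
    polys = cache.tri_polys
    inter = shapely.intersects(region, polys)
    within = shapely.contains_properly(region, polys)
    for j, i in enumerate(nz_index):
        tri = tri_all[i]
        if within[j]:
            out.append(tri)
            continue
        if not inter[j]:
            continue
        clipped = polys[j].intersection(region)
        abc = cache.plane_abc[j]
        flip = signed_area[i] < 0
        for t2 in triangulate_polygon(clipped):
            z = abc[0] * t2[:, 0] + abc[1] * t2[:, 1] + abc[2]
            t3 = np.column_stack([t2, z])
            out.append(t3[::-1] if flip else t3)
    # vertical triangles
    for i in np.nonzero(vertical)[0]:
        out.extend(_clip_vertical_triangle(tri_all[i], region))
    return out


def build_walls(
    mesh: TriangleMesh,
    region,
    facet_segments: list[tuple[np.ndarray, np.ndarray]],
    sil,
) -> list[np.ndarray]:
    """Cut-wall triangles along chain facets bordering ``region``.

    A wall exists wherever exactly one side of the facet lies in the resected
    region; it is the mesh cross-section clipped to the facet extent, oriented
    with its normal pointing out of the region.
    """
    shapely.prepare(region)
    out: list[np.ndarray] = []
    zlo = mesh.bounds[0, 2] - 1.0
    zhi = mesh.bounds[1, 2] + 1.0
    probe = max(1e-6, 10 * SLIT)
    for a2, b2 in facet_segments:
        a2 = np.asarray(a2, dtype=float)
        b2 = np.asarray(b2, dtype=float)
        L = np.linalg.norm(b2 - a2)
        if L < 1e-9:
            continue
        d = (b2 - a2) / L
        n2 = np.array([-d[1], d[0]])
        pieces = LineString([a2, b2]).intersection(sil)
        section = None
        for g in getattr(pieces, "geoms", [pieces]):
            if not isinstance(g, LineString) or g.length < 1e-6:
                continue
            s0 = float((np.asarray(g.coords[0]) - a2) @ d)
            s1 = float((np.asarray(g.coords[-1]) - a2) @ d)
            lo, hi = sorted((s0, s1))
            mid2 = a2 + 0.5 * (lo + hi) * d
            side_pos = region.covers(Point(mid2 + probe * n2))
            side_neg = region.covers(Point(mid2 - probe * n2))
            if side_pos == side_neg:
                continue  # interior notch or fully outside: no wall
            if section is None:
                section = section_polygon(mesh, a2, d)
            wall2d = section.intersection(box(lo, zlo, hi, zhi))
            outward = -n2 if side_pos else n2
            sign = np.dot(np.array([d[1], -d[0]]), outward)
            for t2 in triangulate_polygon(wall2d):
                t3 = np.array([[a2[0] + s * d[0], a2[1] + s * d[1], z] for s, z in t2])
                # CCW in (s,z) maps to 3D normal (d x z) = (d_y, -d_x, 0)
                out.append(t3 if sign > 0 else t3[::-1])
    return out


def split_mesh_prism(
    mesh: TriangleMesh,
    cache: MeshPrismCache,
    region,
    facet_segments: list[tuple[np.ndarray, np.ndarray]],
) -> TriangleMesh:
    """Assemble the resected mesh: clipped surface plus cut walls."""
    tris = clip_mesh_to_region(mesh, cache, region)
    tris += build_walls(mesh, region, facet_segments, cache.sil)
    if not tris:
        raise SplitError("null-split", "empty split result")
    arr = np.asarray(tris)
    verts = arr.reshape(-1, 3)
    faces = np.arange(len(verts), dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(verts, faces)
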