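"""Synthetic bone/tumor mesh pairs for testing and benchmarking.

Three kinds, all emulating an epiphyseal tumor whose xy-footprint partially
protrudes beyond the bone footprint (so the convex-hull warm start is
applicable):

* ``corner_column`` -- cubic bone slab with a box tumor occupying one corner
  column; the optimal two-plane cut and its objective value are known in
  closed form.
* ``eccentric_ellipsoid`` -- cylindrical bone shaft with an off-axis
  ellipsoidal tumor.
* ``concave_bean`` -- cylindrical bone with a two-lobed (peanut cross
  section) tumor whose footprint is genuinely concave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import TriangleMesh

__all__ = ["PhantomSpec", "make_phantom", "box_mesh", "lathe_mesh", "cylinder_mesh"]

KINDS = ("corner_column", "eccentric_ellipsoid", "concave_bean")


@dataclass
class PhantomSpec:
    kind: str = "corner_column"
    resolution: float = 5.0  # target edge length, mm
    seed: int = 0
    bone_size: float = 40.0  # corner_column slab edge
    bone_radius: float = 15.0  # cylindrical bones
    bone_half_height: float = 40.0
    tumor_offset: float = 12.0  # radial offset of the tumor center
    tumor_radii: tuple[float, float, float] = (8.0, 6.0, 10.0)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {KINDS}")


@dataclass
class Phantom:
    bone: TriangleMesh
    tumor: TriangleMesh
    access: np.ndarray
    n_planes: int
    margin_mm: float
    analytic_f: float | None = None
    analytic_vol_b_cut: float | None = None
    spec: PhantomSpec = field(default_factory=PhantomSpec)


# ---------------------------------------------------------------------------
# Meshers
# ---------------------------------------------------------------------------

def box_mesh(lo, hi, resolution: float = 5.0) -> TriangleMesh:
    """Watertight axis-aligned box with gridded faces (~resolution spacing)."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    nd = np.maximum(np.round((hi - lo) / resolution).astype(int), 1)
    nx, ny, nz = (int(v) for v in nd)

    # vertex grid on the 6 faces only, indexed through a dict
    verts: list[np.ndarray] = []
    vid: dict[tuple[int, int, int], int] = {}

    def vert(i, j, k) -> int:
        key = (i, j, k)
        if key not in vid:
            vid[key] = len(verts)
            verts.append(
                np.array(
                    [
                        lo[0] + (hi[0] - lo[0]) * i / nx,
                        lo[1] + (hi[1] - lo[1]) * j / ny,
                        lo[2] + (hi[2] - lo[2]) * k / nz,
                    ]
                )
            )
        return vid[key]

    faces: list[tuple[int, int, int]] = []

    def quad(a, b, c, d, flip):
        if flip:
            a, b, c, d = d, c, b, a
        faces.append((a, b, c))
        faces.append((a, c, d))

    for j in range(ny):  # x = const faces
        for k in range(nz):
            for i0, flip in ((0, True), (nx, False)):
                quad(
                    vert(i0, j, k), vert(i0, j + 1, k),
                    vert(i0, j + 1, k + 1), vert(i0, j, k + 1), flip,
                )
    for i in range(nx):  # y = const faces
        for k in range(nz):
            for j0, flip in ((0, False), (ny, True)):
                quad(
                    vert(i, j0, k), vert(i + 1, j0, k),
                    vert(i + 1, j0, k + 1), vert(i, j0, k + 1), flip,
                )
    for i in range(nx):  # z = const faces
        for j in range(ny):
            for k0, flip in ((0, True), (nz, False)):
                quad(
                    vert(i, j, k0), vert(i + 1, j, k0),
                    vert(i + 1, j + 1, k0), vert(i, j + 1, k0), flip,
                )
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64)).oriented()


def lathe_mesh(
    radius_fn,
    center=(0.0, 0.0, 0.0),
    half_height: float = 10.0,
    n_theta: int = 24,
    n_lat: int = 12,
) -> TriangleMesh:
    """Closed lat-long style surface: xy cross-section radius ``radius_fn(theta)``
    scaled by cos(lat), z = half_height * sin(lat), with pole fans."""
    c = np.asarray(center, dtype=float)
    lats = np.linspace(-np.pi / 2, np.pi / 2, n_lat + 1)[1:-1]
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rows = []
    for lat in lats:
        s = np.cos(lat)
        ring = [
            c + np.array([s * radius_fn(t) * np.cos(t), s * radius_fn(t) * np.sin(t),
                          half_height * np.sin(lat)])
            for t in thetas
        ]
        rows.append(ring)
    verts = [c + np.array([0, 0, -half_height])] + [v for ring in rows for v in ring]
    south = 0
    north = len(verts)
    verts.append(c + np.array([0, 0, half_height]))

    def rv(row, i):
        return 1 + row * n_theta + (i % n_theta)

    faces = []
    for i in range(n_theta):  # south fan
        faces.append((south, rv(0, i + 1), rv(0, i)))
    for row in range(len(rows) - 1):
        for i in range(n_theta):
            a, b = rv(row, i), rv(row, i + 1)
            d, e = rv(row + 1, i), rv(row + 1, i + 1)
            faces.append((a, b, e))
            faces.append((a, e, d))
    last = len(rows) - 1
    for i in range(n_theta):  # north fan
        faces.append((north, rv(last, i), rv(last, i + 1)))
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64)).oriented()


def ellipsoid_mesh(center, radii, n_theta=24, n_lat=14) -> TriangleMesh:
    rx, ry, rz = radii
    mesh = lathe_mesh(
        lambda t: 1.0, center=(0, 0, 0), half_height=1.0, n_theta=n_theta, n_lat=n_lat
    )
    v = mesh.vertices * np.array([rx, ry, rz]) + np.asarray(center, dtype=float)
    return TriangleMesh(v, mesh.faces).oriented()


def cylinder_mesh(
    radius: float, z0: float, z1: float, center_xy=(0.0, 0.0), n_theta: int = 24, n_z: int = 8
) -> TriangleMesh:
    """Closed cylinder with fan caps."""
    cx, cy = center_xy
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(z0, z1, n_z + 1)
    verts = [np.array([cx, cy, z0])]
    for z in zs:
        for t in thetas:
            verts.append(np.array([cx + radius * np.cos(t), cy + radius * np.sin(t), z]))
    top_center = len(verts)
    verts.append(np.array([cx, cy, z1]))

    def rv(row, i):
        return 1 + row * n_theta + (i % n_theta)

    faces = []
    for i in range(n_theta):
        faces.append((0, rv(0, i + 1), rv(0, i)))
    for row in range(n_z):
        for i in range(n_theta):
            a, b = rv(row, i), rv(row, i + 1)
            d, e = rv(row + 1, i), rv(row + 1, i + 1)
            faces.append((a, b, e))
            faces.append((a, e, d))
    for i in range(n_theta):
        faces.append((top_center, rv(n_z, i), rv(n_z, i + 1)))
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64)).oriented()


# ---------------------------------------------------------------------------
# Phantom kinds
# ---------------------------------------------------------------------------

def _corner_column(spec: PhantomSpec) -> Phantom:
    L = spec.bone_size
    bone = box_mesh([0, 0, 0], [L, L, L], spec.resolution)
    tumor = box_mesh([-5, -5, 0], [10, 10, L], min(spec.resolution, 5.0))
    # optimal 2-plane cut: tangent planes x = 10 and y = 10 remove the
    # 10 x 10 x L corner column
    vol_b_cut = 10.0 * 10.0 * L
    analytic_f = vol_b_cut / L**3
    return Phantom(
        bone=bone,
        tumor=tumor,
        access=np.array([0.0, 0.0, 1.0]),
        n_planes=2,
        margin_mm=0.0,
        analytic_f=analytic_f,
        analytic_vol_b_cut=vol_b_cut,
        spec=spec,
    )


def _eccentric_ellipsoid(spec: PhantomSpec) -> Phantom:
    n_theta = max(12, int(round(2 * np.pi * spec.bone_radius / spec.resolution)))
    bone = cylinder_mesh(
        spec.bone_radius,
        -spec.bone_half_height,
        spec.bone_half_height,
        n_theta=n_theta,
        n_z=max(4, int(2 * spec.bone_half_height / (2 * spec.resolution))),
    )
    tumor = ellipsoid_mesh(
        (spec.tumor_offset, 0.0, 0.45 * spec.bone_half_height),
        spec.tumor_radii,
        n_theta=max(14, n_theta // 2),
        n_lat=12,
    )
    if spec.tumor_offset + spec.tumor_radii[0] <= spec.bone_radius:
        raise ValueError("tumor footprint must protrude beyond the bone footprint")
    return Phantom(
        bone=bone, tumor=tumor, access=np.array([0.0, 0.0, 1.0]),
        n_planes=3, margin_mm=1.0, spec=spec,
    )


def _concave_bean(spec: PhantomSpec) -> Phantom:
    R_bone = spec.bone_radius + 3.0
    n_theta = max(16, int(round(2 * np.pi * R_bone / spec.resolution)))
    bone = cylinder_mesh(
        R_bone, -spec.bone_half_height, spec.bone_half_height,
        n_theta=n_theta, n_z=6,
    )

    # peanut cross-section: two lobes along x, concave waist along y
    R = 9.0

    def peanut(t):
        return R * (0.62 + 0.38 * np.cos(2 * t))

    tumor = lathe_mesh(
        peanut,
        center=(spec.tumor_offset, 0.0, 0.4 * spec.bone_half_height),
        half_height=12.0,
        n_theta=max(24, n_theta),
        n_lat=10,
    )
    return Phantom(
        bone=bone, tumor=tumor, access=np.array([0.0, 0.0, 1.0]),
        n_planes=4, margin_mm=1.0, spec=spec,
    )


def make_phantom(spec: PhantomSpec | str) -> Phantom:
    """Generate a watertight bone/tumor pair (plus access direction and, for
    ``corner_column``, the analytic optimum).

    Raises if the tumor does not overlap the bone or does not protrude
    beyond its footprint.
    """
    if isinstance(spec, str):
        spec = PhantomSpec(kind=spec)
    builder = {
        "corner_column": _corner_column,
        "eccentric_ellipsoid": _eccentric_ellipsoid,
        "concave_bean": _concave_bean,
    }[spec.kind]
    ph = builder(spec)
    for name, mesh in (("bone", ph.bone), ("tumor", ph.tumor)):
        if not mesh.is_watertight():
            raise RuntimeError(f"phantom {name} mesh is not watertight")
    # overlap sanity: tumor centroid column must pass through the bone
    from .mesh_core import vertical_lines_hit

    ctr = ph.tumor.centroid()[:2]
    if not vertical_lines_hit(ph.bone, ctr[None, :])[0]:
        raise RuntimeError("tumor does not overlap the bone footprint")
    return ph
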