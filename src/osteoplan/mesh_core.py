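"""Triangle-mesh primitives, STL/PLY I/O and case canonicalization.

All geometry is in millimetres, float64 in memory (STL files are float32 on
disk).  Meshes whose volume is taken must be watertight: every edge shared by
exactly two faces with opposite traversal direction.  Orientation is
normalized so that the signed (divergence-theorem) volume is positive.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MeshError",
    "TriangleMesh",
    "RigidTransform",
    "SurgicalCase",
    "read_mesh",
    "write_mesh",
    "mesh_volume",
    "mesh_centroid",
    "expand_tumor",
    "canonicalize_case",
    "rotation_to_z",
    "vertical_lines_hit",
]


class MeshError(ValueError):
    """Raised for invalid mesh input (non-watertight, degenerate, ...)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R @ p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class TriangleMesh:
    """Closed tessellated surface: ``vertices`` (V, 3) and ``faces`` (F, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")

    # -- basic measures ----------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) triangle corner coordinates."""
        return self.vertices[self.faces]

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def signed_volume(self) -> float:
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def volume(self) -> float:
        if not self.is_watertight():
            raise MeshError(
                f"volume of non-watertight mesh ({self.open_edge_count()} open edges)"
            )
        return abs(self.signed_volume())

    def centroid(self) -> np.ndarray:
        """Volume centroid (divergence theorem over signed tetrahedra)."""
        if not self.is_watertight():
            raise MeshError("centroid of non-watertight mesh")
        t = self.triangles
        d = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2]))
        c = (t[:, 0] + t[:, 1] + t[:, 2]) / 4.0
        vol6 = d.sum()
        if abs(vol6) < 1e-12:
            raise MeshError("centroid of zero-volume mesh")
        return (d[:, None] * c).sum(axis=0) / vol6

    # -- topology ----------------------------------------------------------
    def _edge_counts(self) -> tuple[np.ndarray, np.ndarray]:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        und = np.sort(e, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        return uniq, counts

    def open_edge_count(self) -> int:
        _, counts = self._edge_counts()
        return int((counts != 2).sum())

    def is_watertight(self) -> bool:
        if len(self.faces) == 0:
            return False
        _, counts = self._edge_counts()
        return bool((counts == 2).all())

    def oriented(self) -> "TriangleMesh":
        """Copy with faces flipped if the signed volume is negative."""
        if self.signed_volume() < 0:
            return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy())
        return self.copy()

    def transformed(self, tf: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(tf.apply(self.vertices), self.faces.copy())

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if normalized:
            ln = np.linalg.norm(n, axis=1)
            ln[ln == 0] = 1.0
            n = n / ln[:, None]
        return n

    @classmethod
    def concatenate(cls, meshes: list["TriangleMesh"]) -> "TriangleMesh":
        verts, faces, off = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + off)
            off += len(m.vertices)
        if not verts:
            return cls(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        return cls(np.vstack(verts), np.vstack(faces))


def mesh_volume(mesh: TriangleMesh) -> float:
    """Positive enclosed volume (mm^3) of a watertight, oriented mesh."""
    return mesh.volume()


def mesh_centroid(mesh: TriangleMesh) -> np.ndarray:
    return mesh.centroid()


# ---------------------------------------------------------------------------
# I/O: STL (binary + ASCII) and PLY (ASCII).  STL stores a triangle soup, so
# reading merges bit-identical duplicate vertices to recover connectivity.
# ---------------------------------------------------------------------------

def _merge_vertices(tris: np.ndarray) -> TriangleMesh:
    flat = tris.reshape(-1, 3)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    return TriangleMesh(uniq, inv.reshape(-1, 3))


def _read_stl(path: Path) -> TriangleMesh:
    raw = path.read_bytes()
    is_ascii = raw[:5] == b"solid"
    if is_ascii and len(raw) >= 84:
        # binary files may also start with "solid"; check the face count
        (nf,) = struct.unpack("<I", raw[80:84])
        if 84 + 50 * nf == len(raw):
            is_ascii = False
    if is_ascii:
        coords = []
        for line in raw.decode("ascii", errors="replace").splitlines():
            parts = line.split()
            if parts and parts[0] == "vertex":
                coords.append([float(x) for x in parts[1:4]])
        tris = np.asarray(coords, dtype=float).reshape(-1, 3, 3)
    else:
        (nf,) = struct.unpack("<I", raw[80:84])
        body = np.frombuffer(raw, dtype=np.uint8, count=50 * nf, offset=84)
        rec = body.reshape(nf, 50)[:, 12:48].copy().view("<f4").astype(float)
        tris = rec.reshape(nf, 3, 3)
    return _merge_vertices(tris)


def _write_stl(mesh: TriangleMesh, path: Path, ascii_mode: bool = False) -> None:
    tris = mesh.triangles.astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if ascii_mode:
        lines = ["solid osteoplan"]
        for n, t in zip(normals, tris):
            lines.append(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid osteoplan")
        path.write_text("\n".join(lines) + "\n")
        return
    nf = len(tris)
    buf = bytearray(b"\x00" * 80 + struct.pack("<I", nf))
    rec = np.zeros((nf, 50), dtype=np.uint8)
    rec[:, 0:12] = normals.view(np.uint8).reshape(nf, 12)
    rec[:, 12:48] = tris.reshape(nf, 9).view(np.uint8).reshape(nf, 36)
    buf += rec.tobytes()
    path.write_bytes(bytes(buf))


def _read_ply(path: Path) -> TriangleMesh:
    text = path.read_text().splitlines()
    i, nv, nf = 0, 0, 0
    while text[i].strip() != "end_header":
        parts = text[i].split()
        if parts[:2] == ["element", "vertex"]:
            nv = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            nf = int(parts[2])
        elif parts[:2] == ["format", "binary_little_endian"] or parts[:2] == [
            "format",
            "binary_big_endian",
        ]:
            raise MeshError("only ASCII PLY is supported")
        i += 1
    i += 1
    verts = np.asarray(
        [[float(x) for x in text[i + k].split()[:3]] for k in range(nv)], dtype=float
    )
    faces = []
    for k in range(nf):
        row = [int(x) for x in text[i + nv + k].split()]
        if row[0] != 3:
            raise MeshError("PLY faces must be triangles")
        faces.append(row[1:4])
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64))


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path: str | Path, require_watertight: bool = True) -> TriangleMesh:
    """Read an STL or PLY surface mesh, check watertightness, fix winding.

    Raises :class:`MeshError` (naming the open-edge count) if the mesh is not
    watertight and ``require_watertight`` is true.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        mesh = _read_stl(path)
    elif suffix == ".ply":
        mesh = _read_ply(path)
    else:
        raise MeshError(f"unsupported mesh format: {suffix!r} (use .stl or .ply)")
    if require_watertight and not mesh.is_watertight():
        raise MeshError(
            f"mesh {path.name!r} is not watertight: {mesh.open_edge_count()} open edges"
        )
    return mesh.oriented()


def write_mesh(mesh: TriangleMesh, path: str | Path, ascii_mode: bool = False) -> None:
    """Write STL (binary by default) or ASCII PLY depending on the suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        _write_stl(mesh, path, ascii_mode=ascii_mode)
    elif suffix == ".ply":
        _write_ply(mesh, path)
    else:
        raise MeshError(f"unsupported mesh format: {suffix!r} (use .stl or .ply)")


# ---------------------------------------------------------------------------
# Tumor margin expansion
# ---------------------------------------------------------------------------

def expand_tumor(tumor: TriangleMesh, margin: float) -> TriangleMesh:
    """Expand a watertight tumor mesh outward by ``margin`` millimetres.

    Vertices are displaced along their area-weighted normal, scaled so that
    every incident face plane moves out by at least ``margin`` (mitred
    offset).  This keeps each input surface point at distance >= margin
    inside the output, slightly over-covering at sharp features, which is the
    conservative direction for a safety margin.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if not tumor.is_watertight():
        raise MeshError("expand_tumor requires a watertight mesh")
    tumor = tumor.oriented()
    if margin == 0:
        return tumor.copy()

    fn = tumor.face_normals(normalized=False)  # area-weighted
    vn = np.zeros_like(tumor.vertices)
    for k in range(3):
        np.add.at(vn, tumor.faces[:, k], fn)
    ln = np.linalg.norm(vn, axis=1)
    ln[ln == 0] = 1.0
    vn = vn / ln[:, None]

    # worst-case cosine between the vertex normal and any incident face normal
    fn_unit = tumor.face_normals()
    cos_min = np.ones(len(tumor.vertices))
    for k in range(3):
        dots = np.einsum("ij,ij->i", vn[tumor.faces[:, k]], fn_unit)
        np.minimum.at(cos_min, tumor.faces[:, k], dots)
    cos_min = np.clip(cos_min, 0.2, 1.0)

    out = TriangleMesh(tumor.vertices + (margin / cos_min)[:, None] * vn, tumor.faces.copy())
    if not out.is_watertight():  # pragma: no cover - topology is unchanged
        raise MeshError("offset produced a non-watertight mesh")
    return out


# ---------------------------------------------------------------------------
# Case canonicalization
# ---------------------------------------------------------------------------

def rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix mapping a unit ``direction`` onto +z.

    Rotates about ``direction x z`` so the free azimuth is untouched; the
    antiparallel case falls back to a half-turn about x.
    """
    d = np.asarray(direction, dtype=float).reshape(3)
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        raise ValueError("access direction must be a non-zero vector")
    d = d / nrm
    z = np.array([0.0, 0.0, 1.0])
    c = float(d @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(d, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


@dataclass
class SurgicalCase:
    """Canonicalized planning case: tumor centroid at the origin, access = +z."""

    bone: TriangleMesh
    tumor_raw: TriangleMesh
    tumor_expanded: TriangleMesh
    access_direction: np.ndarray
    n_planes: int
    margin_mm: float
    tumor_centroid: np.ndarray
    transform: RigidTransform = field(default_factory=RigidTransform.identity)
    _geom: object | None = field(default=None, repr=False, compare=False)

    @property
    def vol_bone_total(self) -> float:
        return self.bone.volume()

    @property
    def vol_tumor_total(self) -> float:
        """Total tumor volume used for normalization (margin-expanded model)."""
        return self.tumor_expanded.volume()

    def summary(self) -> dict:
        return {
            "n_planes": int(self.n_planes),
            "margin_mm": float(self.margin_mm),
            "vol_bone_total_mm3": self.vol_bone_total,
            "vol_tumor_total_mm3": self.vol_tumor_total,
            "bone_bounds": self.bone.bounds.tolist(),
            "tumor_bounds": self.tumor_expanded.bounds.tolist(),
        }


def canonicalize_case(
    bone: TriangleMesh,
    tumor: TriangleMesh,
    access: np.ndarray,
    n: int,
    margin: float,
) -> SurgicalCase:
    """Rigidly move the scene so the tumor centroid sits at the origin and the
    surgical access direction becomes +z; expand the tumor by the margin.

    The same transform is applied to bone and tumor so relative anatomy is
    preserved exactly.
    """
    if n < 1:
        raise ValueError("number of planes n must be >= 1")
    access = np.asarray(access, dtype=float).reshape(3)
    if abs(np.linalg.norm(access) - 1.0) > 1e-6:
        nrm = np.linalg.norm(access)
        if nrm < 1e-12:
            raise ValueError("access direction must be a non-zero vector")
        access = access / nrm
    tumor = tumor.oriented()
    bone = bone.oriented()
    if tumor.volume() <= 0:
        raise MeshError("tumor has zero volume")

    R = rotation_to_z(access)
    c = tumor.centroid()
    tf = RigidTransform(R, -R @ c)
    bone_c = bone.transformed(tf)
    tumor_c = tumor.transformed(tf)
    expanded = expand_tumor(tumor_c, margin)
    return SurgicalCase(
        bone=bone_c,
        tumor_raw=tumor_c,
        tumor_expanded=expanded,
        access_direction=np.array([0.0, 0.0, 1.0]),
        n_planes=int(n),
        margin_mm=float(margin),
        tumor_centroid=tumor_c.centroid(),
        transform=tf,
    )


# ---------------------------------------------------------------------------
# Vertical line queries (used by the hull classification and validity checks)
# ---------------------------------------------------------------------------

def vertical_lines_hit(mesh: TriangleMesh, points_xy: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """For each xy point, does the full vertical line through it hit the mesh?

    Pure point-in-projected-triangle test (no 2D silhouette construction), so
    it can serve as the implementation side of a dual-route check.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))[:, :2]
    tri = mesh.triangles[:, :, :2]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    def cr(u, v):
        return u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]

    area2 = np.abs(cr(b - a, c - a))
    out = np.zeros(len(pts), dtype=bool)
    # edge cross products against the point, per triangle
    for i, p in enumerate(pts):
        d1 = cr(b - a, p - a)
        d2 = cr(c - b, p - b)
        d3 = cr(a - c, p - c)
        inside = ((d1 >= -tol) & (d2 >= -tol) & (d3 >= -tol)) | (
            (d1 <= tol) & (d2 <= tol) & (d3 <= tol)
        )
        # zero-area projections would accept everything; exclude them
        out[i] = bool((inside & (area2 > tol)).any())
    return out


def case_to_json(case: SurgicalCase) -> str:
    return json.dumps(case.summary(), indent=2)
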