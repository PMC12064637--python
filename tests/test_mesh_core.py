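import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import _oracles
from osteoplan.mesh_core import (
    MeshError,
    RigidTransform,
    TriangleMesh,
    canonicalize_case,
    expand_tumor,
    mesh_centroid,
    mesh_volume,
    read_mesh,
    rotation_to_z,
    vertical_lines_hit,
    write_mesh,
)
from osteoplan.phantoms import box_mesh, lathe_mesh


def unit_cube():
    return box_mesh([0, 0, 0], [1, 1, 1], resolution=2.0)


def uv_sphere(r=1.0, center=(0, 0, 0), n_theta=48, n_lat=24):
    m = lathe_mesh(lambda t: r, center=center, half_height=r, n_theta=n_theta, n_lat=n_lat)
    return m


class TestIO:
    def test_unit_cube_stl_roundtrip(self, tmp_path):
        cube = unit_cube()
        assert len(cube.faces) == 12
        write_mesh(cube, tmp_path / "cube.stl")
        back = read_mesh(tmp_path / "cube.stl")
        assert len(back.vertices) == 8
        assert len(back.faces) == 12
        assert back.volume() == pytest.approx(1.0, abs=1e-6)

    def test_ascii_stl_roundtrip(self, tmp_path):
        cube = unit_cube()
        write_mesh(cube, tmp_path / "cube.stl", ascii_mode=True)
        back = read_mesh(tmp_path / "cube.stl")
        assert back.volume() == pytest.approx(1.0, abs=1e-6)

    def test_sphere_roundtrip_volume(self, tmp_path):
        sph = uv_sphere()
        write_mesh(sph, tmp_path / "s.stl")
        back = read_mesh(tmp_path / "s.stl")
        assert abs(back.volume() - sph.volume()) / sph.volume() < 1e-6

    def test_ply_roundtrip(self, tmp_path):
        sph = uv_sphere(n_theta=16, n_lat=8)
        write_mesh(sph, tmp_path / "s.ply")
        back = read_mesh(tmp_path / "s.ply")
        assert back.volume() == pytest.approx(sph.volume(), rel=1e-6)

    def test_missing_face_raises_watertight_error(self, tmp_path):
        cube = unit_cube()
        broken = TriangleMesh(cube.vertices, cube.faces[:-1])
        write_mesh(broken, tmp_path / "broken.stl")
        with pytest.raises(MeshError, match="not watertight"):
            read_mesh(tmp_path / "broken.stl")

    def test_unknown_format(self, tmp_path):
        (tmp_path / "m.obj").write_text("")
        with pytest.raises(MeshError, match="unsupported"):
            read_mesh(tmp_path / "m.obj")


class TestVolumeCentroid:
    def test_unit_cube_volume(self):
        assert mesh_volume(unit_cube()) == pytest.approx(1.0)

    def test_sphere_volume_analytic(self):
        # fine tessellation converges on 4*pi/3
        v = mesh_volume(uv_sphere(n_theta=64, n_lat=32))
        assert v == pytest.approx(4 * np.pi / 3, rel=5e-3)

    def test_centroid_of_shifted_cube(self):
        m = box_mesh([2, 3, 4], [4, 5, 6], resolution=2.0)
        assert mesh_centroid(m) == pytest.approx([3, 4, 5])

    def test_volume_matches_column_oracle(self, corner_phantom, ellipsoid_phantom):
        for mesh in (corner_phantom.bone, ellipsoid_phantom.tumor):
            oracle = _oracles.column_volume(mesh, pitch=0.5)
            assert mesh_volume(mesh) == pytest.approx(oracle, rel=0.01)

    def test_non_watertight_volume_raises(self):
        cube = unit_cube()
        broken = TriangleMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(MeshError):
            mesh_volume(broken)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_volume_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mesh = uv_sphere(r=7.0, center=(3, -2, 5), n_theta=24, n_lat=12)
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.uniform(-50, 50, 3)
        moved = mesh.transformed(RigidTransform(R, t))
        assert abs(moved.volume() - mesh.volume()) / mesh.volume() < 1e-9

    def test_orientation_normalized(self):
        cube = unit_cube()
        flipped = TriangleMesh(cube.vertices, cube.faces[:, ::-1])
        assert flipped.signed_volume() < 0
        assert flipped.oriented().signed_volume() > 0


class TestRigidTransform:
    def test_inverse_roundtrip(self):
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        tf = RigidTransform(R, np.array([1.0, -2.0, 3.0]))
        pts = np.random.default_rng(0).normal(size=(20, 3))
        back = tf.inverse().apply(tf.apply(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestCanonicalize:
    def test_identity_rotation_translation(self):
        tumor = uv_sphere(r=2.0, center=(5, 5, 5), n_theta=24, n_lat=12)
        bone = box_mesh([0, 0, 0], [20, 20, 20], resolution=10.0)
        case = canonicalize_case(bone, tumor, [0, 0, 1], 2, 0.0)
        assert case.transform.rotation == pytest.approx(np.eye(3))
        assert case.transform.translation == pytest.approx([-5, -5, -5], abs=1e-9)
        assert case.tumor_centroid == pytest.approx([0, 0, 0], abs=1e-9)

    def test_access_x_maps_to_z(self):
        R = rotation_to_z([1, 0, 0])
        assert R @ np.array([1.0, 0, 0]) == pytest.approx([0, 0, 1], abs=1e-9)
        tumor = uv_sphere(r=2.0, center=(1, 2, 3), n_theta=16, n_lat=8)
        bone = box_mesh([-5, -5, -5], [8, 8, 8], resolution=13.0)
        case = canonicalize_case(bone, tumor, [1, 0, 0], 2, 0.0)
        acc = case.transform.rotation @ np.array([1.0, 0, 0])
        assert acc == pytest.approx([0, 0, 1], abs=1e-9)

    def test_rigidity_preserves_distances(self):
        tumor = uv_sphere(r=2.0, center=(4, -1, 7), n_theta=16, n_lat=8)
        bone = box_mesh([-10, -10, -10], [10, 10, 10], resolution=10.0)
        d_before = np.linalg.norm(bone.centroid() - tumor.centroid())
        case = canonicalize_case(bone, tumor, [0, 1, 0], 2, 0.0)
        d_after = np.linalg.norm(case.bone.centroid() - case.tumor_raw.centroid())
        assert d_after == pytest.approx(d_before, abs=1e-9)

    def test_idempotent(self, corner_case):
        again = canonicalize_case(
            corner_case.bone, corner_case.tumor_raw, [0, 0, 1],
            corner_case.n_planes, corner_case.margin_mm,
        )
        assert again.transform.rotation == pytest.approx(np.eye(3), abs=1e-9)
        assert again.transform.translation == pytest.approx([0, 0, 0], abs=1e-7)

    def test_bad_inputs(self):
        tumor = uv_sphere(r=1.0, n_theta=12, n_lat=6)
        bone = box_mesh([-2, -2, -2], [2, 2, 2], resolution=4.0)
        with pytest.raises(ValueError):
            canonicalize_case(bone, tumor, [0, 0, 0], 2, 0.0)
        with pytest.raises(ValueError):
            canonicalize_case(bone, tumor, [0, 0, 1], 0, 0.0)


class TestExpandTumor:
    def test_zero_margin_identity(self):
        sph = uv_sphere(r=5.0, n_theta=24, n_lat=12)
        out = expand_tumor(sph, 0.0)
        assert out.volume() == pytest.approx(sph.volume(), rel=1e-9)

    def test_sphere_offset_analytic(self):
        # r=10 offset by 2 -> volume of r=12 sphere within 2%
        sph = uv_sphere(r=10.0, n_theta=48, n_lat=24)
        out = expand_tumor(sph, 2.0)
        assert out.volume() == pytest.approx(4 * np.pi / 3 * 12**3, rel=0.02)

    def test_monotone_in_margin(self):
        sph = uv_sphere(r=5.0, n_theta=24, n_lat=12)
        vols = [expand_tumor(sph, m).volume() for m in (0.0, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(vols, vols[1:]))

    def test_surface_distance_postcondition(self):
        # every input vertex ends at least `margin` inside the offset surface:
        # check against the analytic offset sphere radius
        sph = uv_sphere(r=10.0, n_theta=32, n_lat=16)
        out = expand_tumor(sph, 3.0)
        r_out = np.linalg.norm(out.vertices, axis=1)
        r_in = np.linalg.norm(sph.vertices, axis=1)
        assert (r_out - r_in >= 3.0 - 1e-9).all()

    def test_box_margin_covers_faces(self):
        # faces must move out by at least the margin; the mitred corner
        # displacement may overshoot (conservative direction) but boundedly
        box = box_mesh([0, 0, 0], [10, 10, 10], resolution=2.0)
        out = expand_tumor(box, 1.5)
        b = out.bounds
        assert (b[0] <= -1.5 + 1e-9).all()
        assert (b[1] >= 11.5 - 1e-9).all()
        assert (b[0] >= -1.5 * 3).all()
        assert (b[1] <= 10 + 1.5 * 3).all()

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            expand_tumor(uv_sphere(n_theta=12, n_lat=6), -1.0)


class TestVerticalLines:
    def test_hits_and_misses(self, corner_phantom):
        bone = corner_phantom.bone  # [0,40]^3
        pts = np.array([[20.0, 20.0], [20.0, -5.0], [100.0, 100.0]])
        hits = vertical_lines_hit(bone, pts)
        assert hits.tolist() == [True, False, False]

    def test_agreement_with_oracle(self, ellipsoid_phantom, rng):
        bone = ellipsoid_phantom.bone
        lo, hi = bone.bounds[0, :2] - 5, bone.bounds[1, :2] + 5
        pts = rng.uniform(lo, hi, size=(200, 2))
        ours = vertical_lines_hit(bone, pts)
        oracle = _oracles.vertical_hit_oracle(bone, pts)
        # boundary-grazing samples may disagree; interior verdicts must match
        disagree = ours != oracle
        assert disagree.mean() < 0.02
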