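import numpy as np
import pytest

import _oracles
from osteoplan.ach_init import (
    build_ach,
    classify_hull_points,
    preserve_and_order,
    project_and_hull,
    rdp,
    simplify_to_n,
)
from osteoplan.objective import Evaluator
from osteoplan.phantoms import box_mesh, lathe_mesh


class TestProjectAndHull:
    def test_box_tumor_gives_corners(self):
        box = box_mesh([-3, -2, -1], [3, 2, 1], resolution=1.0)
        hull = project_and_hull(box)
        assert len(hull) == 4
        assert sorted(map(tuple, np.abs(hull))) == [(3, 2)] * 4

    def test_sphere_hull_close_to_circle(self):
        sph = lathe_mesh(lambda t: 8.0, half_height=8.0, n_theta=48, n_lat=24)
        hull = project_and_hull(sph)
        r = np.hypot(hull[:, 0], hull[:, 1])
        assert np.abs(r - 8.0).max() / 8.0 < 0.01

    def test_polar_ordered(self):
        box = box_mesh([-3, -2, -1], [3, 2, 1], resolution=1.0)
        hull = project_and_hull(box)
        theta = np.mod(np.arctan2(hull[:, 1], hull[:, 0]), 2 * np.pi)
        assert (np.diff(theta) > 0).all()

    def test_degenerate_projection_raises(self):
        from osteoplan.mesh_core import TriangleMesh

        flatline = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 1], [3, 0, 0]], dtype=float),
            np.array([[0, 1, 2], [0, 2, 3], [0, 3, 2], [0, 2, 1]]),
        )
        with pytest.raises(ValueError, match="degenerate"):
            project_and_hull(flatline)


class TestClassify:
    def test_under_and_outside(self, corner_case):
        pts = np.array([[10.0, 10.0], [-100.0, -100.0]])
        mask = classify_hull_points(pts, corner_case.bone)
        assert mask.tolist() == [True, False]

    def test_silhouette_oracle_agreement(self, ellipsoid_case, rng):
        bone = ellipsoid_case.bone
        lo, hi = bone.bounds[0, :2] - 5, bone.bounds[1, :2] + 5
        pts = rng.uniform(lo, hi, size=(1000, 2))
        ours = classify_hull_points(pts, bone)
        oracle = _oracles.silhouette_contains_oracle(bone, pts)
        assert (ours != oracle).mean() < 0.01  # boundary fuzz only


class TestPreserveAndOrder:
    def test_circular_tttff(self):
        hull = np.array([(1, 0), (0, 1), (-1, 0), (-1, -1), (1, -1)], dtype=float)
        mask = np.array([True, True, True, False, False])
        poly, reason = preserve_and_order(hull, mask)
        assert reason is None
        assert len(poly) == 5
        assert poly[0].tolist() == [1, -1]  # preceding false
        assert poly[-1].tolist() == [-1, -1]  # succeeding false
        assert [tuple(p) for p in poly[1:4]] == [(1, 0), (0, 1), (-1, 0)]

    def test_multiple_runs_infeasible(self):
        hull = np.array([(1, 0), (0, 1), (-1, 0), (0, -1)], dtype=float)
        mask = np.array([True, False, True, False])
        poly, reason = preserve_and_order(hull, mask)
        assert poly is None and reason == "multiple-runs"

    def test_all_true_all_false(self):
        hull = np.ones((4, 2))
        assert preserve_and_order(hull, np.ones(4, bool))[1] == "all-true"
        assert preserve_and_order(hull, np.zeros(4, bool))[1] == "all-false"


class TestRDP:
    def test_collinear_to_endpoints(self):
        pts = np.column_stack([np.linspace(0, 9, 10), np.zeros(10)])
        out = simplify_to_n(pts, n=1)
        assert len(out) == 2
        assert out[0].tolist() == [0, 0] and out[-1].tolist() == [9, 0]

    def test_square_corner_keeps_corner(self):
        pts = np.array([(0, 0), (5, 0), (10, 0), (10, 5), (10, 10)], dtype=float)
        out = simplify_to_n(pts, n=2)
        assert len(out) == 3
        assert out[1].tolist() == [10, 0]

    def test_deviation_bounded_by_epsilon(self, rng):
        pts = np.cumsum(rng.normal(size=(30, 2)), axis=0)
        eps = 1.5
        out = rdp(pts, eps)
        # every input vertex within eps of the simplified chain (brute force)
        for p in pts:
            dmin = np.inf
            for a, b in zip(out[:-1], out[1:]):
                d = b - a
                t = np.clip((p - a) @ d / max(d @ d, 1e-12), 0, 1)
                dmin = min(dmin, np.linalg.norm(a + t * d - p))
            assert dmin <= eps + 1e-9

    def test_pad_when_short(self):
        pts = np.array([(0, 0), (10, 0)], dtype=float)
        out = simplify_to_n(pts, n=3)
        assert len(out) == 4
        assert out[0].tolist() == [0, 0] and out[-1].tolist() == [10, 0]


class TestEndToEnd:
    @pytest.mark.parametrize(
        "case_fixture", ["corner_case", "ellipsoid_case", "bean_case"]
    )
    def test_ach_feasible_and_clears_tumor(self, case_fixture, request):
        case = request.getfixturevalue(case_fixture)
        ach = build_ach(case)
        assert ach.feasible, ach.reason
        assert len(ach.offset_points) == case.n_planes + 1
        ev = Evaluator(case)
        res = ev.evaluate(ach.offset_points.ravel())
        assert not res.penalized
        assert res.vol_T_left <= 1e-3 * case.vol_tumor_total

    def test_preserved_polyline_structure(self, corner_case):
        ach = build_ach(corner_case)
        mask = ach.truth_mask
        assert mask.sum() >= 1
        assert len(ach.preserved_polyline) == mask.sum() + 2

    def test_offset_monotone_f(self, corner_case):
        # offsetting a feasible path radially can only cost more bone
        ach = build_ach(corner_case)
        ev = Evaluator(corner_case)
        base = ev.evaluate(ach.offset_points.ravel())
        pts = ach.offset_points
        unit = pts / np.linalg.norm(pts, axis=1)[:, None]
        further = ev.evaluate((pts + 0.5 * unit).ravel())
        assert not further.penalized
        assert further.f >= base.f - 1e-12

    def test_raw_source_selectable(self, ellipsoid_case):
        ach = build_ach(ellipsoid_case, source="raw")
        assert ach.hull_points is not None
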