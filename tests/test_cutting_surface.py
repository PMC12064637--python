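import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from osteoplan._geom2d import SplitError
from osteoplan.cutting_surface import (
    CuttingPath,
    build_surface,
    order_points_polar,
    orient_facets,
    resected_volumes,
    split_both,
    split_with_surface,
    z_extent_for,
)
from osteoplan.objective import CaseGeometry, Evaluator
from osteoplan.phantoms import box_mesh


def dots_away(surface, centroid=(0.0, 0.0)):
    """dot(normal, midpoint - centroid) per facet (positive = away)."""
    ctr = np.asarray(centroid)
    return [float(f.normal[:2] @ (f.midpoint - ctr)) for f in surface.facets]


def polar(deg, r):
    a = np.deg2rad(deg)
    return [r * np.cos(a), r * np.sin(a)]


class TestOrderPointsPolar:
    def test_basic_example(self):
        path = order_points_polar([(1, 0), (-1, 0), (0, 1)], (0, 0))
        assert path.points.tolist() == [[1, 0], [0, 1], [-1, 0]]

    @settings(max_examples=30, deadline=None)
    @given(st.permutations(list(range(5))))
    def test_permutation_invariance(self, perm):
        pts = np.array([(3, 1), (-2, 2), (-1, -3), (2, -2), (0.5, 2.5)])
        ref = order_points_polar(pts).points
        out = order_points_polar(pts[list(perm)]).points
        assert np.array_equal(ref, out)

    def test_equal_angle_tiebreak_radius(self):
        # same polar angle, radii 1 and 2: nearer point first; brute-force
        # sort on (angle, radius) agrees
        pts = np.array([(2, 2), (1, 1), (0, 3)])
        out = order_points_polar(pts).points
        key = sorted(
            range(3),
            key=lambda i: (np.arctan2(pts[i, 1], pts[i, 0]) % (2 * np.pi),
                           np.hypot(*pts[i])),
        )
        assert np.array_equal(out, pts[key])
        assert out[0].tolist() == [1, 1]

    def test_branch_angle_opens_gap(self):
        pts = np.array([polar(34, 10), polar(145, 10), polar(215, 10), polar(326, 10)])
        out = order_points_polar(pts, branch_angle=0.0).points
        assert np.allclose(out[0], polar(34, 10))
        out2 = order_points_polar(pts, branch_angle=np.pi).points
        assert np.allclose(out2[0], polar(215, 10))

    def test_point_at_center_raises(self):
        with pytest.raises(ValueError, match="centroid"):
            order_points_polar([(0, 0), (1, 1)], (0, 0))


class TestBuildSurface:
    def test_facet_count_and_area(self):
        path = CuttingPath([(0, 0.1), (3, 0.1), (3, 4.1)])
        surf = build_surface(path, (-10, 10))
        assert surf.n_facets == 2
        areas = [f.length * (f.z_max - f.z_min) for f in surf.facets]
        assert areas == pytest.approx([60.0, 80.0])

    def test_collinear_points_identical_normals(self):
        path = CuttingPath([(-5, 3), (0, 3), (5, 3)])
        surf = orient_facets(build_surface(path, (-1, 1)), (0, 0))
        n0, n1 = surf.facets[0].normal, surf.facets[1].normal
        assert n0 == pytest.approx(n1)
        assert n0[:2] @ np.array([0, 1]) > 0  # away from origin

    def test_degenerate_segment_flagged(self):
        path = CuttingPath([(1, 1), (1 + 1e-9, 1), (2, 3)])
        surf = build_surface(path, (0, 1))
        assert surf.facets[0].degenerate and not surf.facets[1].degenerate

    def test_bad_z_extent(self):
        with pytest.raises(ValueError):
            build_surface(CuttingPath([(0, 1), (1, 1)]), (5, 5))

    def test_square_corner_normals(self):
        path = CuttingPath([(10, -20), (10, 10), (-20, 10)])
        surf = orient_facets(build_surface(path, (-1, 1)), (0, 0))
        assert surf.facets[0].normal == pytest.approx([1, 0, 0])
        assert surf.facets[1].normal == pytest.approx([0, 1, 0])


class TestOrientFacets:
    def test_case_all_gaps_small_all_away(self):
        pts = [polar(6, 10), polar(96, 10), polar(186, 10), polar(276, 10)]
        surf = orient_facets(build_surface(CuttingPath(pts), (-1, 1)), (0, 0))
        assert all(d > 0 for d in dots_away(surf))

    def test_case_reflex_gap_at_ending_facet(self):
        pts = [polar(0, 30), polar(10, 30), polar(20, 30), polar(350, 30)]
        surf = orient_facets(build_surface(CuttingPath(pts), (-1, 1)), (0, 0))
        d = dots_away(surf)
        assert d[2] > 0  # the reflex ending facet points away
        assert d[0] < 0 and d[1] < 0  # the others face the centroid

    def test_case_reflex_intermediate_next_inside_triangle(self):
        pts = [polar(0, 30), polar(20, 30), polar(230, 30), polar(240, 3), polar(250, 30)]
        surf = orient_facets(build_surface(CuttingPath(pts), (-1, 1)), (0, 0))
        d = dots_away(surf)
        assert d[1] < 0  # reflex intermediate facet faces the centroid
        assert d[0] > 0 and d[2] > 0 and d[3] > 0

    def test_case_reflex_intermediate_next_outside_triangle(self):
        pts = [polar(0, 30), polar(20, 30), polar(230, 30), polar(240, 20), polar(250, 30)]
        surf = orient_facets(build_surface(CuttingPath(pts), (-1, 1)), (0, 0))
        assert all(d > 0 for d in dots_away(surf))

    def test_idempotent(self):
        pts = [polar(0, 30), polar(10, 30), polar(20, 30), polar(350, 30)]
        surf = orient_facets(build_surface(CuttingPath(pts), (-1, 1)), (0, 0))
        before = [f.normal.copy() for f in surf.facets]
        surf = orient_facets(surf, (0, 0))
        for n_old, f in zip(before, surf.facets):
            assert n_old == pytest.approx(f.normal)


class TestSplit:
    def test_half_cube(self):
        cube = box_mesh([-1, -1, -1], [1, 1, 1], resolution=1.0)
        surf = build_surface(CuttingPath([(-2, 0), (2, 0)]), (-1.2, 1.2))
        surf = orient_facets(surf, (0, -0.5))
        part = split_with_surface(cube, surf, (0, -0.5, 0))
        assert abs(part.signed_volume()) == pytest.approx(4.0, rel=1e-6)

    def test_surface_outside_footprint_signals_empty(self):
        cube = box_mesh([-1, -1, -1], [1, 1, 1], resolution=1.0)
        surf = build_surface(CuttingPath([(5, -5), (5, 5)]), (-1.2, 1.2))
        with pytest.raises(SplitError) as err:
            split_with_surface(cube, surf, (0, 0, 0))
        assert err.value.reason == "no-contact"

    def test_conservation_on_random_paths(self, corner_case, rng):
        ev = Evaluator(corner_case)
        geom = CaseGeometry.for_case(corner_case)
        bone = corner_case.bone
        total = bone.volume()
        checked = 0
        for _ in range(60):
            raw = rng.uniform(-25, 40, size=6)
            res = ev.evaluate(raw)
            if res.penalized:
                continue
            path = order_points_polar(raw.reshape(-1, 2), (0, 0), geom.branch_angle)
            surf = orient_facets(
                build_surface(path, z_extent_for(bone)), (0, 0)
            )
            try:
                part, rest = split_both(bone, surf, (0, 0, 0), cache=geom.bone_cache)
            except SplitError:
                continue
            v1, v2 = abs(part.signed_volume()), abs(rest.signed_volume())
            assert abs(v1 + v2 - total) / total < 1e-3
            checked += 1
            if checked >= 5:
                break
        assert checked >= 3

    def test_convex_path_voxel_equivalence(self, corner_case, corner_optimal_path):
        from osteoplan import _geom2d

        geom = CaseGeometry.for_case(corner_case)
        path = order_points_polar(corner_optimal_path, (0, 0), geom.branch_angle)
        region = _geom2d.split_region(geom.bone_cache.sil, path.points, (0, 0))
        vol = _geom2d.prism_volume(geom.bone_cache, region)
        poly = np.asarray(region.exterior.coords)
        oracle = _oracles.column_volume_in_polygon(corner_case.bone, poly, pitch=0.5)
        assert vol == pytest.approx(oracle, rel=0.015)


class TestResectedVolumes:
    def test_corner_column_optimum(self, corner_case, corner_optimal_path):
        vol_b, vol_t_left = resected_volumes(corner_case, CuttingPath(corner_optimal_path))
        assert vol_b == pytest.approx(4000.0, rel=0.02)
        assert vol_t_left <= 1e-3 * corner_case.vol_tumor_total

    def test_cyclic_relabel_invariance(self, corner_case, corner_optimal_path):
        base = resected_volumes(corner_case, CuttingPath(corner_optimal_path))
        rolled = resected_volumes(
            corner_case, CuttingPath(np.roll(corner_optimal_path, 1, axis=0))
        )
        assert rolled == pytest.approx(base)

    def test_path_enclosing_tumor_leaves_none(self, corner_case):
        # wide corner path well clear of the tumor footprint
        path = CuttingPath([(15.0, -23.0), (15.0, 15.0), (-23.0, 15.0)])
        vol_b, vol_t_left = resected_volumes(corner_case, path)
        assert vol_t_left <= 1e-3 * corner_case.vol_tumor_total
        assert vol_b > 4000.0
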