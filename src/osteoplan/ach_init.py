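"""Approximated-convex-hull (ACH) warm start for the optimizer.

Pipeline: project the (margin-expanded) tumor to xy, take its 2D convex
hull, mark hull points whose vertical line hits the bone, keep the single
contiguous run of marked points plus the two flanking unmarked ones,
simplify to n+1 points with Ramer-Douglas-Peucker, and push the result
radially outward until the tumor is fully cleared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .cutting_surface import CuttingPath
from .mesh_core import SurgicalCase, TriangleMesh, vertical_lines_hit
from .objective import Evaluator, ObjectiveConfig

__all__ = [
    "ACHResult",
    "project_and_hull",
    "classify_hull_points",
    "preserve_and_order",
    "simplify_to_n",
    "rdp",
    "offset_outward",
    "build_ach",
]


@dataclass
class ACHResult:
    hull_points: np.ndarray
    truth_mask: np.ndarray
    preserved_polyline: np.ndarray | None
    simplified_points: np.ndarray | None
    offset_points: np.ndarray | None
    feasible: bool
    reason: str | None = None
    offset_delta: float | None = None
    f: float | None = None

    @property
    def path(self) -> CuttingPath | None:
        if self.offset_points is None:
            return None
        return CuttingPath(self.offset_points)

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "hull_points": arr(self.hull_points),
            "truth_mask": arr(self.truth_mask),
            "preserved_polyline": arr(self.preserved_polyline),
            "simplified_points": arr(self.simplified_points),
            "offset_points": arr(self.offset_points),
            "feasible": self.feasible,
            "reason": self.reason,
            "offset_delta": self.offset_delta,
            "f": self.f,
        }


def project_and_hull(tumor: TriangleMesh, center=(0.0, 0.0)) -> np.ndarray:
    """2D convex hull of the tumor's projected vertices, polar-ordered.

    The hull is returned counter-clockwise starting from the smallest polar
    angle about ``center`` (the tumor centroid, i.e. the origin after
    canonicalization).
    """
    pts = tumor.vertices[:, :2]
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate tumor projection: {exc}") from exc
    hp = pts[hull.vertices]  # CCW order from qhull
    ctr = np.asarray(center, dtype=float)
    theta = np.mod(np.arctan2(hp[:, 1] - ctr[1], hp[:, 0] - ctr[0]), 2 * np.pi)
    start = int(np.argmin(theta))
    return np.roll(hp, -start, axis=0)


def classify_hull_points(hull: np.ndarray, bone: TriangleMesh) -> np.ndarray:
    """True per hull point iff its full vertical line intersects the bone."""
    return vertical_lines_hit(bone, hull)


def preserve_and_order(hull: np.ndarray, mask: np.ndarray):
    """Open polyline: preceding-false, the contiguous true run, succeeding-false.

    Returns (polyline, reason); reason is set and polyline None when the mask
    is all-true, all-false, or contains multiple separated true runs.
    """
    mask = np.asarray(mask, dtype=bool)
    m = len(mask)
    if mask.all():
        return None, "all-true"
    if not mask.any():
        return None, "all-false"
    # circular runs of consecutive true values
    starts = [i for i in range(m) if mask[i] and not mask[i - 1]]
    if len(starts) != 1:
        return None, "multiple-runs"
    s = starts[0]
    run = []
    i = s
    while mask[i % m]:
        run.append(i % m)
        i += 1
    idx = [(s - 1) % m] + run + [(run[-1] + 1) % m]
    return hull[idx].copy(), None


def _point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = b - a
    dd = float(d @ d)
    if dd < 1e-24:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ d / dd, 0.0, 1.0)
    return np.linalg.norm(a + t[:, None] * d - pts, axis=1)


def rdp(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Classic Ramer-Douglas-Peucker simplification, endpoints preserved."""
    pts = np.asarray(points, dtype=float)
    if len(pts) <= 2:
        return pts.copy()
    dists = _point_segment_distance(pts[1:-1], pts[0], pts[-1])
    imax = int(np.argmax(dists))
    if dists[imax] <= epsilon:
        return np.vstack([pts[0], pts[-1]])
    left = rdp(pts[: imax + 2], epsilon)
    right = rdp(pts[imax + 1 :], epsilon)
    return np.vstack([left[:-1], right])


def simplify_to_n(polyline: np.ndarray, n: int, resolution: float = 1e-4) -> np.ndarray:
    """Simplify to exactly n+1 points.

    The tolerance is the smallest epsilon (bisection at ``resolution`` mm)
    whose RDP output has at most n+1 points; if the result falls short,
    midpoints of the longest segments are inserted until n+1 is reached.
    """
    pts = np.asarray(polyline, dtype=float)
    target = n + 1
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    if len(pts) > target:
        lo, hi = 0.0, float(np.ptp(pts, axis=0).max()) + 1.0
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if len(rdp(pts, mid)) <= target:
                hi = mid
            else:
                lo = mid
        pts = rdp(pts, hi)
    while len(pts) < target:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        k = int(np.argmax(seg))
        mid = 0.5 * (pts[k] + pts[k + 1])
        pts = np.vstack([pts[: k + 1], mid, pts[k + 1 :]])
    return pts


def offset_outward(
    points: np.ndarray,
    evaluator: Evaluator,
    step: float = 0.1,
    max_delta: float = 10.0,
    vol_tol_rel: float = 1e-6,
):
    """Push points radially outward by the smallest grid delta that clears the
    tumor (vol_T_left = 0 within mesh tolerance) without penalty.

    Returns (offset_points, delta, result) or (None, None, last_result).
    """
    pts = np.asarray(points, dtype=float)
    r = np.linalg.norm(pts, axis=1)
    r[r < 1e-9] = 1.0
    unit = pts / r[:, None]
    tol = vol_tol_rel * evaluator.geom.vol_tumor_total
    last = None
    delta = step
    while delta <= max_delta + 1e-12:
        cand = pts + delta * unit
        res = evaluator.evaluate(cand.ravel())
        last = res
        if not res.penalized and res.vol_T_left <= tol:
            return cand, delta, res
        delta += step
    return None, None, last


def build_ach(
    case: SurgicalCase,
    obj_config: ObjectiveConfig | None = None,
    source: str = "expanded",
) -> ACHResult:
    """Full warm-start construction for a canonicalized case.

    ``source`` selects which tumor model is projected in the first step:
    ``"expanded"`` (default; the path must clear the safety margin) or
    ``"raw"``.
    """
    tumor = case.tumor_expanded if source == "expanded" else case.tumor_raw
    evaluator = Evaluator(case, obj_config)
    try:
        hull = project_and_hull(tumor, (0.0, 0.0))
    except ValueError as exc:
        return ACHResult(
            hull_points=np.zeros((0, 2)),
            truth_mask=np.zeros(0, dtype=bool),
            preserved_polyline=None,
            simplified_points=None,
            offset_points=None,
            feasible=False,
            reason=str(exc),
        )
    mask = classify_hull_points(hull, case.bone)
    polyline, reason = preserve_and_order(hull, mask)
    if polyline is None:
        return ACHResult(hull, mask, None, None, None, feasible=False, reason=reason)
    simplified = simplify_to_n(polyline, case.n_planes)
    offset_pts, delta, res = offset_outward(simplified, evaluator)
    if offset_pts is None:
        return ACHResult(
            hull, mask, polyline, simplified, None,
            feasible=False, reason="no-clearing-offset",
        )
    return ACHResult(
        hull_points=hull,
        truth_mask=mask,
        preserved_polyline=polyline,
        simplified_points=simplified,
        offset_points=offset_pts,
        feasible=True,
        offset_delta=delta,
        f=res.f,
    )
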