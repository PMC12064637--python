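"""The scalar fitness the optimizer minimizes.

For a feasible path, f = vol_B_cut / vol_B_tot + K * vol_T_left / vol_T_tot;
invalid configurations receive a fixed penalty value that strictly dominates
every feasible f (which is bounded by 1 + K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geom2d
from ._geom2d import MeshPrismCache, SplitError
from .cutting_surface import build_surface, order_points_polar, orient_facets, z_extent_for
from .mesh_core import SurgicalCase
from .validity import ValidityReport, validate_configuration

DEFAULT_K = 100.0

REASON_FACET_MISS = "facet-miss"
REASON_SELF_INTERSECTION = "self-intersection-hit"
REASON_NULL_SPLIT = "null-split"
REASON_DEGENERATE = "degenerate-chain"
REASON_MULTI_REFLEX = "multi-reflex-gap"


@dataclass
class ObjectiveConfig:
    K: float = DEFAULT_K
    penalty_value: float = field(default=None)  # type: ignore[assignment]
    vol_B_tot: float | None = None
    vol_T_tot: float | None = None

    def __post_init__(self) -> None:
        if self.penalty_value is None:
            self.penalty_value = 10.0 + self.K
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.penalty_value <= 1.0 + self.K:
            raise ValueError("penalty_value must exceed 1 + K to dominate feasible f")


@dataclass
class ObjectiveResult:
    f: float
    vol_B_cut: float
    vol_T_left: float
    penalized: bool
    reason: str | None
    validity: ValidityReport | None

    def to_dict(self) -> dict:
        return {
            "f": self.f,
            "vol_B_cut_mm3": self.vol_B_cut,
            "vol_T_left_mm3": self.vol_T_left,
            "penalized": self.penalized,
            "reason": self.reason,
            "validity": self.validity.to_dict() if self.validity else None,
        }


class CaseGeometry:
    """Cached per-case geometry shared across thousands of evaluations."""

    def __init__(self, case: SurgicalCase):
        self.case = case
        self.bone_cache = MeshPrismCache.build(case.bone)
        self.tumor_cache = MeshPrismCache.build(case.tumor_expanded)
        # one split region must serve both meshes: the resected tumor part is
        # only truly removed together with the bone around it, so the chain
        # has to separate the union footprint of the scene
        self.scene_sil = self.bone_cache.sil.union(self.tumor_cache.sil)
        self.vol_bone_total = self.bone_cache.total_volume()
        self.vol_tumor_total = self.tumor_cache.total_volume()
        self.z_extent = z_extent_for(case.bone)
        # chain opening faces the tumor's protrusion: from the bone footprint
        # centroid toward the tumor centroid (the origin)
        c = self.bone_cache.sil.centroid
        self.branch_angle = float(np.arctan2(-c.y, -c.x)) if c.x**2 + c.y**2 > 1e-12 else 0.0

    @classmethod
    def for_case(cls, case: SurgicalCase) -> "CaseGeometry":
        if case._geom is None or getattr(case._geom, "case", None) is not case:
            case._geom = cls(case)
        return case._geom


class Evaluator:
    """Bound objective: raw 2(n+1) coordinates -> ObjectiveResult."""

    def __init__(self, case: SurgicalCase, config: ObjectiveConfig | None = None):
        self.case = case
        self.geom = CaseGeometry.for_case(case)
        config = config or ObjectiveConfig()
        if config.vol_B_tot is None:
            config.vol_B_tot = self.geom.vol_bone_total
        if config.vol_T_tot is None:
            config.vol_T_tot = self.geom.vol_tumor_total
        self.config = config

    def _penalized(self, reason: str, validity: ValidityReport | None = None) -> ObjectiveResult:
        return ObjectiveResult(
            f=self.config.penalty_value,
            vol_B_cut=float("nan"),
            vol_T_left=float("nan"),
            penalized=True,
            reason=reason,
            validity=validity,
        )

    def evaluate(self, raw_points: np.ndarray) -> ObjectiveResult:
        raw = np.asarray(raw_points, dtype=float).ravel()
        if not np.isfinite(raw).all():
            return self._penalized(REASON_DEGENERATE)
        try:
            path = order_points_polar(raw.reshape(-1, 2), (0.0, 0.0), self.geom.branch_angle)
        except ValueError:
            return self._penalized(REASON_DEGENERATE)

        surface = build_surface(path, self.geom.z_extent)
        surface = orient_facets(surface, (0.0, 0.0))
        if surface.invalid_reason:
            return self._penalized(REASON_MULTI_REFLEX)
        if all(f.degenerate for f in surface.facets):
            return self._penalized(REASON_DEGENERATE)

        report = validate_configuration(
            self.case.bone,
            self.case.tumor_expanded,
            surface,
            bone_sil=self.geom.bone_cache.sil,
        )
        if report.degenerate_overlap:
            return self._penalized(REASON_DEGENERATE, report)
        if not report.all_facets_cut:
            return self._penalized(REASON_FACET_MISS, report)
        if report.self_intersection_hits_mesh:
            return self._penalized(REASON_SELF_INTERSECTION, report)

        try:
            region = _geom2d.split_region(self.geom.scene_sil, path.points, (0.0, 0.0))
            vol_b_cut = _geom2d.prism_volume(self.geom.bone_cache, region)
            vol_t_cut = _geom2d.prism_volume(self.geom.tumor_cache, region)
        except SplitError as err:
            return self._penalized(
                REASON_NULL_SPLIT if err.reason != "no-contact" else REASON_FACET_MISS,
                report,
            )

        vol_t_left = max(self.geom.vol_tumor_total - vol_t_cut, 0.0)
        f = (
            vol_b_cut / self.config.vol_B_tot
            + self.config.K * vol_t_left / self.config.vol_T_tot
        )
        return ObjectiveResult(
            f=float(f),
            vol_B_cut=float(vol_b_cut),
            vol_T_left=float(vol_t_left),
            penalized=False,
            reason=None,
            validity=report,
        )

    __call__ = evaluate


def evaluate(
    raw_points: np.ndarray, case: SurgicalCase, config: ObjectiveConfig | None = None
) -> ObjectiveResult:
    """One-shot fitness evaluation for raw path coordinates."""
    return Evaluator(case, config).evaluate(raw_points)
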