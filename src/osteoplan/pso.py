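"""Particle swarm optimizer over the 2(n+1) path coordinates.

Supports a constant coefficient schedule (the c1 + c2 = 4 grid) and a
variable schedule interpolating inertia and the cognitive/social weights
linearly from exploration to exploitation.  A warm-start path may replace
one particle's initial position.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .cutting_surface import CuttingPath
from .mesh_core import SurgicalCase
from .objective import Evaluator, ObjectiveConfig, ObjectiveResult

__all__ = [
    "PSOConfig",
    "OptimizationResult",
    "coefficient_schedule",
    "optimize",
    "run_experiment",
    "constant_grid_configs",
]

VARIABLE_OMEGA = (0.9, 0.4)
VARIABLE_C1 = (2.5, 0.5)
VARIABLE_C2 = (0.5, 2.5)


@dataclass
class PSOConfig:
    n_particles: int = 150
    n_iterations: int = 100
    schedule_kind: str = "variable"  # "constant" | "variable"
    omega: float = 0.8
    c1: float = 2.0
    c2: float = 2.0
    omega_range: tuple[float, float] = VARIABLE_OMEGA  # hi -> lo
    c1_range: tuple[float, float] = VARIABLE_C1  # hi -> lo
    c2_range: tuple[float, float] = VARIABLE_C2  # lo -> hi
    bounds: np.ndarray | None = None  # (2, 2) xy box; default: bone bbox
    seed: int = 0
    warm_start: CuttingPath | None = None
    velocity_clamp_frac: float = 0.2  # of the box diagonal, per component

    def __post_init__(self) -> None:
        if self.schedule_kind not in ("constant", "variable"):
            raise ValueError("schedule_kind must be 'constant' or 'variable'")
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("particles and iterations must be positive")


def coefficient_schedule(iteration: int, config: PSOConfig) -> tuple[float, float, float]:
    """(omega, c1, c2) at a given iteration.

    Constant schedules return the configured values; variable schedules
    interpolate linearly across iterations, omega and c1 high -> low and c2
    low -> high.
    """
    if config.schedule_kind == "constant":
        return (config.omega, config.c1, config.c2)
    T = max(config.n_iterations - 1, 1)
    t = min(max(iteration, 0), T) / T
    omega = config.omega_range[0] + t * (config.omega_range[1] - config.omega_range[0])
    c1 = config.c1_range[0] + t * (config.c1_range[1] - config.c1_range[0])
    c2 = config.c2_range[0] + t * (config.c2_range[1] - config.c2_range[0])
    return (omega, c1, c2)


@dataclass
class OptimizationResult:
    best_path: CuttingPath
    best_objective: ObjectiveResult
    history: np.ndarray  # best f after each iteration, non-increasing
    mean_history: np.ndarray
    penalized_fraction: np.ndarray
    config: PSOConfig
    wall_time: float
    feasible: bool

    def to_dict(self) -> dict:
        return {
            "best_path": self.best_path.points.tolist(),
            "best_objective": self.best_objective.to_dict(),
            "history": self.history.tolist(),
            "wall_time_s": self.wall_time,
            "feasible": self.feasible,
            "config": {
                "n_particles": self.config.n_particles,
                "n_iterations": self.config.n_iterations,
                "schedule_kind": self.config.schedule_kind,
                "omega": self.config.omega,
                "c1": self.config.c1,
                "c2": self.config.c2,
                "seed": self.config.seed,
                "warm_start": self.config.warm_start is not None,
            },
        }


def _default_bounds(case: SurgicalCase) -> np.ndarray:
    b = case.bone.bounds
    return np.array([[b[0, 0], b[0, 1]], [b[1, 0], b[1, 1]]])


def optimize(
    case: SurgicalCase,
    obj_config: ObjectiveConfig | None = None,
    pso_config: PSOConfig | None = None,
    objective_fn=None,
) -> OptimizationResult:
    """Run the swarm and return the best-ever solution.

    ``objective_fn`` may replace the geometric objective (raw vector ->
    object with an ``f`` attribute or a float) for testing.
    """
    cfg = pso_config or PSOConfig()
    evaluator = None
    if objective_fn is None:
        evaluator = Evaluator(case, obj_config)

        def objective_fn(x):
            return evaluator.evaluate(x)

    dim = 2 * (case.n_planes + 1)
    bounds = np.asarray(cfg.bounds if cfg.bounds is not None else _default_bounds(case))
    lo = np.tile(bounds[0], case.n_planes + 1)
    hi = np.tile(bounds[1], case.n_planes + 1)
    diag = float(np.linalg.norm(bounds[1] - bounds[0]))
    vmax = cfg.velocity_clamp_frac * diag

    rng = np.random.default_rng(cfg.seed)
    pos = rng.uniform(lo, hi, size=(cfg.n_particles, dim))
    vel = np.zeros_like(pos)
    if cfg.warm_start is not None:
        ws = cfg.warm_start.points.ravel()
        if ws.size != dim:
            raise ValueError("warm start size does not match 2(n+1)")
        pos[0] = np.clip(ws, lo, hi)

    def f_of(x) -> tuple[float, object]:
        res = objective_fn(x)
        return (float(getattr(res, "f", res)), res)

    pbest = pos.copy()
    pbest_f = np.empty(cfg.n_particles)
    results = [None] * cfg.n_particles
    history, mean_hist, pen_frac = [], [], []
    t0 = time.perf_counter()

    fs = np.empty(cfg.n_particles)
    for i in range(cfg.n_particles):
        fs[i], results[i] = f_of(pos[i])
    pbest_f[:] = fs
    gbest_i = int(np.argmin(pbest_f))
    gbest = pbest[gbest_i].copy()
    gbest_f = float(pbest_f[gbest_i])
    gbest_res = results[gbest_i]

    for it in range(cfg.n_iterations):
        omega, c1, c2 = coefficient_schedule(it, cfg)
        r1 = rng.random((cfg.n_particles, dim))
        r2 = rng.random((cfg.n_particles, dim))
        vel = omega * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        np.clip(vel, -vmax, vmax, out=vel)
        pos = pos + vel
        under, over = pos < lo, pos > hi
        vel[under | over] = 0.0
        np.clip(pos, lo, hi, out=pos)

        cur_pen = np.zeros(cfg.n_particles, dtype=bool)
        for i in range(cfg.n_particles):
            fs[i], res_i = f_of(pos[i])
            cur_pen[i] = bool(getattr(res_i, "penalized", False))
            if fs[i] < pbest_f[i]:
                pbest_f[i] = fs[i]
                pbest[i] = pos[i]
                results[i] = res_i
                if fs[i] < gbest_f:
                    gbest_f = float(fs[i])
                    gbest = pos[i].copy()
                    gbest_res = res_i
        history.append(gbest_f)
        mean_hist.append(float(fs.mean()))
        pen_frac.append(float(cur_pen.mean()))

    wall = time.perf_counter() - t0
    best_path = CuttingPath(gbest.reshape(-1, 2))
    feasible = not getattr(gbest_res, "penalized", False)
    if not isinstance(gbest_res, ObjectiveResult) and evaluator is not None:
        gbest_res = evaluator.evaluate(gbest)
    return OptimizationResult(
        best_path=best_path,
        best_objective=gbest_res,
        history=np.asarray(history),
        mean_history=np.asarray(mean_hist),
        penalized_fraction=np.asarray(pen_frac),
        config=cfg,
        wall_time=wall,
        feasible=feasible,
    )


def constant_grid_configs(base: PSOConfig | None = None) -> dict[str, PSOConfig]:
    """The coefficient study grid: 9 constant configs with omega = 0.8 and
    c1 + c2 = 4, plus the variable schedule."""
    base = base or PSOConfig()
    configs: dict[str, PSOConfig] = {
        "variable": replace(base, schedule_kind="variable"),
    }
    for c1 in (4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0.0):
        c2 = 4.0 - c1
        configs[f"c1={c1:g},c2={c2:g}"] = replace(
            base, schedule_kind="constant", omega=0.8, c1=c1, c2=c2
        )
    return configs


@dataclass
class ExperimentRow:
    label: str
    mean: float
    std: float
    ci_half_width: float
    finals: list[float] = field(default_factory=list)


def run_experiment(
    case: SurgicalCase,
    configs: dict[str, PSOConfig],
    repeats: int = 10,
    obj_config: ObjectiveConfig | None = None,
    objective_fn=None,
) -> list[ExperimentRow]:
    """Repeat each config with distinct seeds; summarize final f.

    The confidence interval is mean +/- 1.96 * SD / sqrt(repeats) (normal
    approximation); SD uses ddof=1 and is 0 for a single repeat.
    """
    rows = []
    for label, cfg in configs.items():
        finals = []
        for r in range(repeats):
            run_cfg = replace(cfg, seed=cfg.seed + 1000 * r)
            res = optimize(case, obj_config, run_cfg, objective_fn=objective_fn)
            finals.append(float(res.history[-1]))
        arr = np.asarray(finals)
        std = float(arr.std(ddof=1)) if repeats > 1 else 0.0
        rows.append(
            ExperimentRow(
                label=label,
                mean=float(arr.mean()),
                std=std,
                ci_half_width=1.96 * std / np.sqrt(repeats),
                finals=finals,
            )
        )
    return rows
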