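"""Command-line workbench: plan, evaluate, make-phantom, experiment.

Configuration precedence is CLI flag > config file > documented default; the
effective values are echoed into every report for provenance.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import typer
import yaml

from .ach_init import build_ach
from .cutting_surface import (
    CuttingPath,
    build_surface,
    facet_planes_json,
    orient_facets,
    path_from_csv,
    path_to_csv,
    resected_volumes,
    split_with_surface,
    z_extent_for,
)
from .mesh_core import SurgicalCase, canonicalize_case, read_mesh, write_mesh
from .objective import CaseGeometry, Evaluator, ObjectiveConfig
from .phantoms import KINDS, PhantomSpec, make_phantom
from .pso import PSOConfig, constant_grid_configs, optimize, run_experiment

app = typer.Typer(add_completion=False, help=__doc__)


def _load_case(case_file: Path, n_planes=None, margin=None, access=None) -> SurgicalCase:
    doc = yaml.safe_load(case_file.read_text())
    base = case_file.parent
    bone = read_mesh(base / doc["bone"])
    tumor = read_mesh(base / doc["tumor"])
    acc = access if access is not None else doc.get("access", [0, 0, 1])
    n = n_planes if n_planes is not None else int(doc.get("n_planes", 2))
    m = margin if margin is not None else float(doc.get("margin_mm", 0.0))
    if n < 1:
        raise typer.BadParameter("n_planes must be >= 1")
    return canonicalize_case(bone, tumor, np.asarray(acc, dtype=float), n, m)


def _parse_access(value: str | None):
    if value is None:
        return None
    parts = [float(v) for v in value.split(",")]
    if len(parts) != 3:
        raise typer.BadParameter("access must be 'x,y,z'")
    return parts


def _pso_config_from(doc: dict, **overrides) -> PSOConfig:
    cfg = PSOConfig()
    fields = {
        "n_particles", "n_iterations", "schedule_kind", "omega", "c1", "c2", "seed",
    }
    updates = {k: v for k, v in doc.items() if k in fields}
    cfg = replace(cfg, **updates)
    updates = {k: v for k, v in overrides.items() if v is not None}
    return replace(cfg, **updates)


@app.command()
def plan(
    case_file: Path = typer.Argument(..., exists=True, readable=True),
    config: Path | None = typer.Option(None, help="YAML file with PSO/objective settings"),
    out_dir: Path = typer.Option(Path("plan_out"), help="output directory"),
    n_planes: int | None = typer.Option(None, "--n-planes"),
    margin: float | None = typer.Option(None, "--margin"),
    access: str | None = typer.Option(None, "--access", help="x,y,z"),
    particles: int | None = typer.Option(None, "--particles"),
    iterations: int | None = typer.Option(None, "--iterations"),
    schedule: str | None = typer.Option(None, "--schedule"),
    c1: float | None = typer.Option(None, "--c1"),
    c2: float | None = typer.Option(None, "--c2"),
    omega: float | None = typer.Option(None, "--omega"),
    seed: int = typer.Option(0, "--seed"),
    no_ach: bool = typer.Option(False, "--no-ach", help="disable the warm start"),
    k_weight: float | None = typer.Option(None, "--k-weight"),
):
    """Full pipeline: canonicalize, ACH warm start, PSO, export artifacts."""
    doc = yaml.safe_load(config.read_text()) if config else {}
    case = _load_case(case_file, n_planes, margin, _parse_access(access))
    obj_cfg = ObjectiveConfig(K=k_weight if k_weight is not None else doc.get("K", 100.0))
    pso_cfg = _pso_config_from(
        doc,
        n_particles=particles,
        n_iterations=iterations,
        schedule_kind=schedule,
        c1=c1,
        c2=c2,
        omega=omega,
        seed=seed,
    )

    ach = None
    if not no_ach:
        ach = build_ach(case, obj_cfg)
        if not ach.feasible:
            typer.echo(f"warning: ACH warm start infeasible ({ach.reason}); "
                       "proceeding with random initialization", err=True)
    warm = ach.path if (ach is not None and ach.feasible) else None
    pso_cfg = replace(pso_cfg, warm_start=warm)

    result = optimize(case, obj_cfg, pso_cfg)

    out_dir.mkdir(parents=True, exist_ok=True)
    geom = CaseGeometry.for_case(case)
    from .cutting_surface import order_points_polar

    best = order_points_polar(result.best_path.points, (0.0, 0.0), geom.branch_angle)
    surface = orient_facets(build_surface(best, z_extent_for(case.bone)), (0.0, 0.0))
    (out_dir / "path.csv").write_text(path_to_csv(best))
    log_lines = ["iteration,best_f,mean_f,penalized_fraction"]
    for i, (bf, mf, pf) in enumerate(
        zip(result.history, result.mean_history, result.penalized_fraction)
    ):
        log_lines.append(f"{i},{bf:.9g},{mf:.9g},{pf:.4f}")
    (out_dir / "iterations.csv").write_text("\n".join(log_lines) + "\n")
    (out_dir / "facet_planes.json").write_text(json.dumps(facet_planes_json(surface), indent=2))
    if result.feasible:
        resected = split_with_surface(case.bone, surface, (0, 0, 0), cache=geom.bone_cache)
        write_mesh(resected, out_dir / "bone_resected.stl")

    report = {
        "case": case.summary(),
        "ach": ach.to_dict() if ach is not None else None,
        "warm_start_used": warm is not None,
        "optimization": result.to_dict(),
        "objective_config": {"K": obj_cfg.K, "penalty_value": obj_cfg.penalty_value},
        "outputs": {
            "path_csv": str(out_dir / "path.csv"),
            "facet_planes_json": str(out_dir / "facet_planes.json"),
        },
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    typer.echo(f"best f = {result.history[-1]:.6f} (feasible={result.feasible}) "
               f"-> {out_dir / 'report.json'}")
    if not result.feasible:
        raise typer.Exit(code=1)


@app.command()
def evaluate(
    case_file: Path = typer.Argument(..., exists=True),
    path_csv: Path = typer.Argument(..., exists=True),
    n_planes: int | None = typer.Option(None, "--n-planes"),
    margin: float | None = typer.Option(None, "--margin"),
    k_weight: float = typer.Option(100.0, "--k-weight"),
):
    """Evaluate an externally provided cutting path with full validity detail."""
    case = _load_case(case_file, n_planes, margin)
    path = path_from_csv(path_csv.read_text())
    res = Evaluator(case, ObjectiveConfig(K=k_weight)).evaluate(path.points.ravel())
    typer.echo(json.dumps(res.to_dict(), indent=2))
    if res.penalized:
        raise typer.Exit(code=1)


@app.command("make-phantom")
def make_phantom_cmd(
    kind: str = typer.Argument(..., help=f"one of {', '.join(KINDS)}"),
    out_dir: Path = typer.Argument(Path("phantom_out")),
    resolution: float = typer.Option(5.0, "--resolution"),
    seed: int = typer.Option(0, "--seed"),
):
    """Generate a synthetic bone/tumor pair and its case description."""
    ph = make_phantom(PhantomSpec(kind=kind, resolution=resolution, seed=seed))
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mesh(ph.bone, out_dir / "bone.stl")
    write_mesh(ph.tumor, out_dir / "tumor.stl")
    case = {
        "bone": "bone.stl",
        "tumor": "tumor.stl",
        "access": [float(v) for v in ph.access],
        "n_planes": int(ph.n_planes),
        "margin_mm": float(ph.margin_mm),
    }
    if ph.analytic_f is not None:
        case["analytic_f"] = float(ph.analytic_f)
    (out_dir / "case.yaml").write_text(yaml.safe_dump(case, sort_keys=False))
    typer.echo(f"wrote {out_dir}/bone.stl, tumor.stl, case.yaml")


@app.command()
def experiment(
    case_file: Path = typer.Argument(..., exists=True),
    out_csv: Path = typer.Option(Path("experiment.csv"), "--out"),
    repeats: int = typer.Option(10, "--repeats"),
    particles: int = typer.Option(150, "--particles"),
    iterations: int = typer.Option(100, "--iterations"),
    seed: int = typer.Option(0, "--seed"),
):
    """Coefficient-schedule sweep: variable plus the 9 constant c1+c2=4 configs."""
    case = _load_case(case_file)
    base = PSOConfig(n_particles=particles, n_iterations=iterations, seed=seed)
    rows = run_experiment(case, constant_grid_configs(base), repeats=repeats)
    lines = ["config,mean,std,ci_half_width"]
    for row in rows:
        lines.append(f"{row.label},{row.mean:.6f},{row.std:.6f},{row.ci_half_width:.6f}")
    out_csv.write_text("\n".join(lines) + "\n")
    typer.echo(f"wrote {out_csv}")


if __name__ == "__main__":
    app()
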