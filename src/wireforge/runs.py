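"""High-level run drivers: execute a configured study and write artifacts.

A run directory contains the generated design(s) as PLY + labelled JSON,
the per-proposal trace as CSV, and a manifest echoing the effective
configuration and seed — enough to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .anneal import AnnealProblem, anneal
from .config import ProblemConfig
from .errors import ObjectiveCountError
from .meshio import export_design, to_dict
from .mosa import MOSAProblem, run_mosa
from .objectives import porosity, scaffold_usage, variation_index
from .mesh import DesignState, estimate_scaffold_nt


def _analysis(state: DesignState) -> dict:
    vals = {
        "n_vertices": state.n_vertices,
        "n_edges": state.n_edges,
        "n_faces": state.n_faces,
        "scaffold_nt": estimate_scaffold_nt(state),
        "porosity": porosity(state),
        "variation_index": variation_index(state),
        "scaffold_usage": scaffold_usage(state),
        "box_volume_nm3": state.box.volume,
    }
    return {k: (float(v) if isinstance(v, float) else v) for k, v in vals.items()}


def _manifest(config: ProblemConfig, seed: int, files: list[str], extra: dict) -> dict:
    return {
        "software": {"name": "wireforge", "version": __version__},
        "seed": seed,
        "config": config.raw,
        "defaults_applied": config.defaults_applied,
        "edge_length_model": {
            "rise_nm": 0.34,
            "rounding": "half-to-even",
            "normalization": "edge lengths divided by their mean (variation index)",
            "std": "population",
        },
        "files": files,
        **extra,
    }


def run_generate(config: ProblemConfig, outdir, seed: int | None = None) -> dict:
    """Single-objective shape annealing; writes design, trace and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    state = config.initial_state()
    problem = AnnealProblem(
        state, config.ruleset, config.constraints, config.objectives[0], config.schedule
    )
    result = anneal(problem, rng)

    files = []
    for name, fmt in (("design.ply", "ply"), ("design.json", "json")):
        export_design(result.best_state, outdir / name, fmt)
        files.append(name)
    result.trace.to_csv(outdir / "trace.csv")
    files.append("trace.csv")
    manifest = _manifest(
        config, seed, files + ["manifest.json"],
        {
            "mode": "generate",
            "objective": {"name": problem.objective.name,
                          "direction": problem.objective.direction},
            "t0": result.t0,
            "best_energy": result.best_energy,
            "proposals": len(result.trace),
            "best_design": _analysis(result.best_state),
        },
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def run_pareto(config: ProblemConfig, outdir, seed: int | None = None) -> dict:
    """Multi-objective shape annealing; writes the archive and manifest."""
    if not 2 <= len(config.objectives) <= 3:
        raise ObjectiveCountError(
            f"{len(config.objectives)} objectives configured; multi-objective "
            "shape annealing is validated with two or three"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    state = config.initial_state()
    problem = MOSAProblem(
        state, config.ruleset, config.constraints, config.objectives, config.schedule,
        return_to_base_every=config.return_to_base_every,
        archive_capacity=config.archive_capacity,
    )
    result = run_mosa(problem, rng)

    files = []
    members = []
    for i, entry in enumerate(result.archive.members):
        name = f"pareto_{i:04d}.ply"
        export_design(entry.state, outdir / name, "ply")
        files.append(name)
        members.append(
            {
                "file": name,
                "objectives": dict(zip([o.name for o in config.objectives], entry.vector)),
                "design": _analysis(entry.state),
                "mesh": to_dict(entry.state),
            }
        )
    result.trace.to_csv(outdir / "trace.csv")
    files.append("trace.csv")
    manifest = _manifest(
        config, seed, files + ["archive.json", "manifest.json"],
        {
            "mode": "pareto",
            "objectives": [{"name": o.name, "direction": o.direction}
                           for o in config.objectives],
            "t0": list(result.t0),
            "archive_size": len(result.archive),
            "proposals": len(result.trace),
        },
    )
    (outdir / "archive.json").write_text(
        json.dumps({"members": members}, indent=2) + "\n"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def write_report(run_dir, out_path=None) -> Path:
    """Plot the optimisation trace (objective + scaffold estimate) of a run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run_dir = Path(run_dir)
    trace = pd.read_csv(run_dir / "trace.csv")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    out_path = Path(out_path) if out_path else run_dir / "report.png"

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    if manifest["mode"] == "generate":
        axes[0].plot(trace["iteration"], trace["energy"], lw=0.7, label="current")
        axes[0].plot(trace["iteration"], trace["best_energy"], lw=1.2, label="best")
        axes[0].set_ylabel(manifest["objective"]["name"])
        axes[0].legend()
    else:
        for name in [o["name"] for o in manifest["objectives"]]:
            axes[0].plot(trace["iteration"], trace[name], lw=0.7, label=name)
        axes[0].set_ylabel("objective energies")
        axes[0].legend()
    axes[1].plot(trace["iteration"], trace["scaffold_nt"], lw=0.7, color="tab:green")
    axes[1].set_ylabel("estimated scaffold (nt)")
    axes[1].set_xlabel("iteration")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
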