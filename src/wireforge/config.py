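"""Problem configuration: schema validation and run assembly.

A design problem is declared in one YAML/JSON document.  The loader
validates the schema strictly — unknown keys are rejected with the full
key path — fills defaults, and records which defaults were applied so a
run manifest can echo the complete effective configuration.
"""

from __future__ import annotations

import importlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import yaml

from .anneal import AnnealingSchedule
from .constraints import ConstraintSet, M13MP18_NT
from .errors import SchemaError, UnknownObjectiveError
from .fixtures import fixture_cube_corners, fixture_parallelepiped_midfaces
from .grammar import ALL_RULES, RuleSet
from .mesh import (
    BoundingBox,
    DesignState,
    EDGE_TYPES,
    EdgeTypeSpec,
    ExcludedRegion,
    initialize_design,
)
from .objectives import ObjectiveSpec, get_objective

_TOP_KEYS = {
    "seed", "box", "edge_type", "preserved", "excluded", "rules",
    "constraints", "objectives", "schedule", "mosa", "output",
}


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise SchemaError(key, message)


def _check_keys(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    _require(not unknown, path, f"unknown keys {sorted(unknown)} (allowed: {sorted(allowed)})")


def _point(value, key) -> tuple[float, float, float]:
    _require(
        isinstance(value, (list, tuple)) and len(value) == 3,
        key, "expected a 3-element [x, y, z] point",
    )
    return tuple(float(x) for x in value)


def _import_callable(spec: str, key: str) -> Callable:
    _require(isinstance(spec, str) and ":" in spec, key, "expected 'module.path:attribute'")
    mod_name, attr = spec.split(":", 1)
    try:
        mod = importlib.import_module(mod_name)
        return getattr(mod, attr)
    except (ImportError, AttributeError) as exc:
        raise SchemaError(key, f"cannot import {spec!r}: {exc}") from exc


@dataclass
class ProblemConfig:
    """Validated problem definition with all defaults resolved."""

    seed: int
    box: BoundingBox
    edge_type: EdgeTypeSpec
    preserved_vertices: list[tuple[float, float, float]]
    preserved_edges: list[tuple[tuple[float, float, float], tuple[float, float, float]]]
    excluded: list[ExcludedRegion]
    ruleset: RuleSet
    constraints: ConstraintSet
    objectives: list[ObjectiveSpec]
    schedule: AnnealingSchedule
    return_to_base_every: int | None = 5
    archive_capacity: int | None = None
    defaults_applied: list[str] = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    def initial_state(self) -> DesignState:
        return initialize_design(
            self.preserved_vertices,
            self.preserved_edges,
            excluded=self.excluded,
            box=self.box,
            edge_type=self.edge_type,
            constraints=self.constraints,
        )


def load_config(path) -> ProblemConfig:
    """Load and validate a YAML/JSON problem file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    _require(isinstance(data, dict), "<root>", "configuration must be a mapping")
    return parse_config(data)


def parse_config(data: dict) -> ProblemConfig:
    defaults: list[str] = []
    _check_keys(data, _TOP_KEYS, "<root>")

    def default(key: str, value):
        defaults.append(f"{key} = {value!r}")
        return value

    seed = int(data.get("seed", default("seed", 0)))

    # ---- bounding box
    boxd = data.get("box")
    _require(isinstance(boxd, dict), "box", "a box mapping {a, b, c, gamma} is required")
    _check_keys(boxd, {"a", "b", "c", "gamma", "origin"}, "box")
    for k in ("a", "b", "c"):
        _require(k in boxd and float(boxd[k]) > 0, f"box.{k}", "positive length required")
    gamma = float(boxd.get("gamma", default("box.gamma", 90.0)))
    _require(0 < gamma < 180, "box.gamma", "must lie in (0, 180) degrees")
    origin = _point(boxd["origin"], "box.origin") if "origin" in boxd else (0.0, 0.0, 0.0)
    box = BoundingBox(float(boxd["a"]), float(boxd["b"]), float(boxd["c"]), gamma, origin)

    # ---- edge type
    et = data.get("edge_type", default("edge_type", "2HB"))
    if isinstance(et, str):
        _require(et in EDGE_TYPES, "edge_type", f"unknown edge type {et!r}")
        edge_type = EDGE_TYPES[et]
    else:
        _require(isinstance(et, dict), "edge_type", "string name or mapping required")
        _check_keys(
            et,
            {"name", "helices_per_edge", "bundle_diameter", "min_edge_nt", "scaffold_passes"},
            "edge_type",
        )
        edge_type = EdgeTypeSpec(
            str(et.get("name", "custom")),
            int(et["helices_per_edge"]),
            float(et["bundle_diameter"]),
            int(et.get("min_edge_nt", 31)),
            int(et["scaffold_passes"]) if "scaffold_passes" in et else None,
        )

    # ---- preserved regions
    pres = data.get("preserved")
    _require(isinstance(pres, dict), "preserved", "a preserved-region mapping is required")
    _check_keys(pres, {"vertices", "edges", "fixture"}, "preserved")
    vertices: list[tuple[float, float, float]] = []
    if "fixture" in pres:
        fx = pres["fixture"]
        _require(isinstance(fx, dict) and len(fx) == 1, "preserved.fixture",
                 "one fixture mapping expected")
        (fname, fargs), = fx.items()
        if fname == "cube_corners":
            _check_keys(fargs, {"side"}, "preserved.fixture.cube_corners")
            vertices += fixture_cube_corners(float(fargs["side"]))
        elif fname == "parallelepiped_midfaces":
            _check_keys(fargs, {"a", "b", "c", "gamma"},
                        "preserved.fixture.parallelepiped_midfaces")
            vertices += fixture_parallelepiped_midfaces(
                float(fargs["a"]), float(fargs["b"]), float(fargs["c"]),
                float(fargs.get("gamma", 90.0)),
            )
        else:
            raise SchemaError("preserved.fixture", f"unknown fixture {fname!r}")
    for i, v in enumerate(pres.get("vertices", [])):
        vertices.append(_point(v, f"preserved.vertices[{i}]"))
    edges = []
    for i, e in enumerate(pres.get("edges", [])):
        _require(isinstance(e, (list, tuple)) and len(e) == 2,
                 f"preserved.edges[{i}]", "expected a pair of points")
        edges.append((_point(e[0], f"preserved.edges[{i}][0]"),
                      _point(e[1], f"preserved.edges[{i}][1]")))
    _require(len(vertices) + 2 * len(edges) >= 4, "preserved",
             "at least 4 preserved points are required to triangulate a start")

    # ---- excluded regions
    excluded = []
    for i, ex in enumerate(data.get("excluded", [])):
        _check_keys(ex, {"min", "max"}, f"excluded[{i}]")
        excluded.append(ExcludedRegion(_point(ex["min"], f"excluded[{i}].min"),
                                       _point(ex["max"], f"excluded[{i}].max")))

    # ---- rules
    rd = dict(data.get("rules", default("rules", {})))
    _check_keys(rd, {"enabled", "weights", "extension", "box_moves"}, "rules")
    enabled = tuple(rd.get("enabled", ("extend_vertex", "edge_flip", "divide_face",
                                       "merge_vertex")))
    for r in enabled:
        _require(r in ALL_RULES, "rules.enabled", f"unknown rule {r!r}")
    ext = dict(rd.get("extension", {}))
    _check_keys(ext, {"k_min", "k_max"}, "rules.extension")
    bm = dict(rd.get("box_moves", {}))
    _check_keys(bm, {"enabled", "box_step", "gamma_step", "bounds"}, "rules.box_moves")
    bounds = RuleSet().box_bounds
    if "bounds" in bm:
        _check_keys(bm["bounds"], {"a", "b", "c", "gamma"}, "rules.box_moves.bounds")
        bounds = {**bounds, **{k: tuple(float(x) for x in v) for k, v in bm["bounds"].items()}}
    ruleset = RuleSet(
        enabled=enabled,
        weights={k: float(v) for k, v in rd.get("weights", {}).items()},
        k_min=int(ext.get("k_min", 1)),
        k_max=int(ext.get("k_max", 20)),
        allow_box_moves=bool(bm.get("enabled", False)) or "resize_box" in enabled,
        box_step=float(bm.get("box_step", 1.0)),
        gamma_step=float(bm.get("gamma_step", 2.0)),
        box_bounds=bounds,
    )

    # ---- constraints
    cd = dict(data.get("constraints", default("constraints", {})))
    _check_keys(cd, {"scaffold_budget", "min_edge_nt", "repulsion_cutoff_nm", "custom"},
                "constraints")
    budget = int(cd.get("scaffold_budget", default("constraints.scaffold_budget", M13MP18_NT)))
    _require(budget > 0, "constraints.scaffold_budget", "must be a positive nucleotide count")
    cutoff = cd.get("repulsion_cutoff_nm")
    if cutoff is not None:
        cutoff = float(cutoff)
        _require(cutoff >= 0, "constraints.repulsion_cutoff_nm", "must be non-negative")
    custom = []
    for i, spec in enumerate(cd.get("custom", [])):
        fn = _import_callable(spec, f"constraints.custom[{i}]")
        custom.append((spec, fn))
    constraints = ConstraintSet(
        scaffold_budget=budget,
        min_edge_nt=int(cd["min_edge_nt"]) if "min_edge_nt" in cd else None,
        repulsion_cutoff=cutoff,
        excluded=tuple(excluded),
        custom=tuple(custom),
    )

    # ---- objectives
    od = data.get("objectives", default("objectives", [{"name": "porosity"}]))
    _require(isinstance(od, list) and od, "objectives", "a non-empty list is required")
    objectives = []
    for i, o in enumerate(od):
        _check_keys(o, {"name", "direction", "params", "callable"}, f"objectives[{i}]")
        direction = o.get("direction", "minimize")
        _require(direction in ("minimize", "maximize"), f"objectives[{i}].direction",
                 "must be minimize or maximize")
        if "callable" in o:
            fn = _import_callable(o["callable"], f"objectives[{i}].callable")
            objectives.append(ObjectiveSpec(o["name"], direction, fn, o.get("params")))
        else:
            try:
                objectives.append(get_objective(o["name"], direction, o.get("params")))
            except UnknownObjectiveError as exc:
                raise UnknownObjectiveError(f"objectives[{i}].name: {exc}") from exc

    # ---- schedule
    sd = dict(data.get("schedule", default("schedule", {})))
    _check_keys(sd, {"t0", "alpha", "stage_length", "total_iterations", "ramp_fraction",
                     "stall_stages", "max_retries"}, "schedule")
    schedule = AnnealingSchedule(
        t0=float(sd["t0"]) if sd.get("t0") is not None else None,
        alpha=float(sd.get("alpha", 0.95)),
        stage_length=int(sd.get("stage_length", 50)),
        total_iterations=int(sd.get("total_iterations", 20000)),
        ramp_fraction=float(sd.get("ramp_fraction", 0.3)),
        stall_stages=sd.get("stall_stages", 3),
        max_retries=int(sd.get("max_retries", 25)),
    )

    # ---- mosa options
    md = dict(data.get("mosa", {}))
    _check_keys(md, {"return_to_base_every", "archive_capacity"}, "mosa")

    return ProblemConfig(
        seed=seed,
        box=box,
        edge_type=edge_type,
        preserved_vertices=vertices,
        preserved_edges=edges,
        excluded=excluded,
        ruleset=ruleset,
        constraints=constraints,
        objectives=objectives,
        schedule=schedule,
        return_to_base_every=md.get("return_to_base_every", 5),
        archive_capacity=md.get("archive_capacity"),
        defaults_applied=defaults,
        raw=data,
    )
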