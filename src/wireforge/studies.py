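"""Reference design studies.

Two standard benchmark problems exercise the whole framework:

* the **cube porosity study** — single-objective porosity minimisation in
  a fixed 50 nm cubic bounding box, 2HB edges, preserved vertices at the
  cube corners, an M13mp18 scaffold budget (7249 nt) and a 2.5 nm
  inter-edge repulsion cutoff.  The optimum fills the box with as much
  DNA as the scaffold allows, so the scaffold estimate presses against
  the budget while porosity falls;
* the **trade-off studies** — multi-objective runs from the
  parallelepiped-midface start with bounding-box dimension moves
  enabled, trading porosity (utility) against either edge-length
  uniformity (variation index) or manufacturability (scaffold usage).
"""

from __future__ import annotations

import numpy as np

from .anneal import AnnealProblem, AnnealResult, AnnealingSchedule, anneal
from .constraints import ConstraintSet, M13MP18_NT
from .fixtures import fixture_cube_corners, fixture_parallelepiped_midfaces
from .grammar import RuleSet
from .mesh import BoundingBox, EDGE_TYPES, EdgeTypeSpec, initialize_design
from .mosa import MOSAProblem, MOSAResult, run_mosa
from .objectives import get_objective

#: side of the cubic bounding box for the single-objective study, nm
CUBE_SIDE_NM = 50.0
#: inter-edge repulsion cutoff, nm
REPULSION_CUTOFF_NM = 2.5


def _schedule(proposals: int) -> AnnealingSchedule:
    return AnnealingSchedule(total_iterations=proposals, stall_stages=None)


def cube_porosity_problem(
    proposals: int = 20000,
    edge_type: EdgeTypeSpec | None = None,
    scaffold_budget: int = M13MP18_NT,
) -> AnnealProblem:
    """Build the single-objective porosity-minimisation problem."""
    edge_type = edge_type or EDGE_TYPES["2HB"]
    constraints = ConstraintSet(
        scaffold_budget=scaffold_budget, repulsion_cutoff=REPULSION_CUTOFF_NM
    )
    state = initialize_design(
        fixture_cube_corners(CUBE_SIDE_NM),
        box=BoundingBox(CUBE_SIDE_NM, CUBE_SIDE_NM, CUBE_SIDE_NM),
        edge_type=edge_type,
        constraints=constraints,
    )
    return AnnealProblem(
        state, RuleSet(), constraints, get_objective("porosity"), _schedule(proposals)
    )


def run_cube_porosity(seed: int, proposals: int = 20000, **kwargs) -> AnnealResult:
    problem = cube_porosity_problem(proposals, **kwargs)
    return anneal(problem, np.random.default_rng(seed))


def tradeoff_problem(
    objectives: tuple[str, str] = ("variation_index", "porosity"),
    proposals: int = 20000,
    edge_type: EdgeTypeSpec | None = None,
    scaffold_budget: int = M13MP18_NT,
) -> MOSAProblem:
    """Build a bi-objective study from the parallelepiped-midface start
    with bounding-box moves (a, b, c, gamma) enabled."""
    edge_type = edge_type or EDGE_TYPES["2HB"]
    constraints = ConstraintSet(scaffold_budget=scaffold_budget)
    s = CUBE_SIDE_NM
    state = initialize_design(
        fixture_parallelepiped_midfaces(s, s, s),
        box=BoundingBox(s, s, s),
        edge_type=edge_type,
        constraints=constraints,
    )
    return MOSAProblem(
        state,
        RuleSet(allow_box_moves=True),
        constraints,
        [get_objective(name) for name in objectives],
        _schedule(proposals),
    )


def run_tradeoff(
    seed: int,
    objectives: tuple[str, str] = ("variation_index", "porosity"),
    proposals: int = 20000,
    **kwargs,
) -> MOSAResult:
    problem = tradeoff_problem(objectives, proposals, **kwargs)
    return run_mosa(problem, np.random.default_rng(seed))
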