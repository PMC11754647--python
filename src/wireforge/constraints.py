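"""Feasibility checking for candidate designs.

Three built-in constraint groups mirror what a wireframe-origami pipeline
has to guarantee before a mesh can be handed to a sequence-design tool:

* topological  — the estimated scaffold demand stays within the available
  scaffold (M13mp18 by default, 7249 nt) and every edge is long enough in
  base pairs for automated staple routing;
* spatial      — every vertex lies inside the bounding box and no edge
  passes through an excluded region;
* repulsion    — non-adjacent helix bundles keep a minimum separation so
  electrostatic repulsion between backbones does not destabilise the fold.

User-defined predicates extend the set through ``ConstraintSet.custom``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .errors import CustomConstraintError
from .mesh import (
    BASE_RISE_NM,
    DesignState,
    ExcludedRegion,
    estimate_scaffold_nt,
    min_nonadjacent_edge_distance,
)

log = logging.getLogger(__name__)

#: length of the M13mp18 single-stranded scaffold, in nucleotides
M13MP18_NT = 7249


class Violation(NamedTuple):
    constraint: str
    measured: float
    bound: float


class FeasibilityReport(NamedTuple):
    feasible: bool
    violations: tuple[Violation, ...]

    @staticmethod
    def ok() -> "FeasibilityReport":
        return FeasibilityReport(True, ())

    @staticmethod
    def of(violations: Sequence[Violation]) -> "FeasibilityReport":
        v = tuple(violations)
        return FeasibilityReport(not v, v)


@dataclass(frozen=True)
class ConstraintSet:
    """Bundle of all feasibility requirements for one design problem."""

    scaffold_budget: int = M13MP18_NT
    min_edge_nt: int | None = None      # None -> take the edge type's floor
    repulsion_cutoff: float | None = None  # nm; None disables the check
    excluded: tuple[ExcludedRegion, ...] = ()
    custom: tuple[tuple[str, Callable[[DesignState], bool]], ...] = ()

    def __post_init__(self):
        if self.scaffold_budget <= 0:
            raise ValueError("scaffold_budget must be positive")
        if self.repulsion_cutoff is not None and self.repulsion_cutoff < 0:
            raise ValueError("repulsion_cutoff must be non-negative")
        object.__setattr__(self, "excluded", tuple(self.excluded))
        object.__setattr__(self, "custom", tuple(self.custom))


def check_topological(state: DesignState, cs: ConstraintSet) -> FeasibilityReport:
    """Scaffold-budget and minimum-edge-length constraints."""
    violations: list[Violation] = []
    n_nt = estimate_scaffold_nt(state)
    if n_nt > cs.scaffold_budget:
        violations.append(Violation("scaffold_length", n_nt, cs.scaffold_budget))
    floor = cs.min_edge_nt if cs.min_edge_nt is not None else state.edge_type.min_edge_nt
    lengths = state.edge_lengths()
    if len(lengths):
        bp = np.rint(lengths / BASE_RISE_NM).astype(int)
        short = int(bp.min())
        if short < floor:
            violations.append(Violation("min_edge", short, floor))
    return FeasibilityReport.of(violations)


def check_spatial(state: DesignState, cs: ConstraintSet) -> FeasibilityReport:
    """Bounding-box containment and excluded-region avoidance."""
    violations: list[Violation] = []
    ids, pts = state.vertex_array()
    if len(pts):
        inside = state.box.contains(pts)
        n_out = int((~inside).sum())
        if n_out:
            violations.append(Violation("bounding_box", n_out, 0))
    if cs.excluded:
        _, p, q = state.edge_endpoints()
        hits = 0
        for region in cs.excluded:
            for a, b in zip(p, q):
                if region.intersects_segment(a, b):
                    hits += 1
        if hits:
            violations.append(Violation("excluded_region", hits, 0))
    return FeasibilityReport.of(violations)


def check_repulsion(state: DesignState, cutoff: float) -> FeasibilityReport:
    """Minimum separation between non-adjacent edges (helix bundles)."""
    d = min_nonadjacent_edge_distance(state)
    if d < cutoff:
        return FeasibilityReport.of([Violation("repulsion", d, cutoff)])
    return FeasibilityReport.ok()


def is_feasible(state: DesignState, cs: ConstraintSet) -> FeasibilityReport:
    """Evaluate every constraint group and report all violations.

    A user predicate that raises is logged, wrapped in a
    :class:`CustomConstraintError` violation entry, and counts as a
    failure — a broken predicate must never admit an infeasible state.
    """
    violations: list[Violation] = []
    violations.extend(check_topological(state, cs).violations)
    violations.extend(check_spatial(state, cs).violations)
    if cs.repulsion_cutoff is not None:
        violations.extend(check_repulsion(state, cs.repulsion_cutoff).violations)
    for name, predicate in cs.custom:
        try:
            ok = bool(predicate(state))
        except Exception as exc:  # noqa: BLE001 - user code boundary
            err = CustomConstraintError(f"custom constraint {name!r} raised: {exc!r}")
            log.warning("%s", err)
            violations.append(Violation(f"custom:{name}:error", math.nan, 0))
            continue
        if not ok:
            violations.append(Violation(f"custom:{name}", 0, 1))
    return FeasibilityReport.of(violations)


def repulsion_predicate(cutoff: float) -> Callable[[DesignState], bool]:
    """Example custom constraint: linear-repulsion distance threshold.

    Equivalent to setting ``repulsion_cutoff`` on the constraint set; kept
    as a worked example of the custom-constraint API, which receives the
    full design state with vertex positions attached.
    """

    def _check(state: DesignState) -> bool:
        return min_nonadjacent_edge_distance(state) >= cutoff

    return _check
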