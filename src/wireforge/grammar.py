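"""Graph-grammar rules that evolve a design state.

The rule family keeps every state a closed triangulated surface while
reaching arbitrary genus-0 shapes:

* ``extend_vertex``  — displace a free vertex by an integer multiple of the
  0.34 nm base-pair rise along a direction (the quantised node-extension
  move, so candidate edge lengths change by whole-nucleotide amounts);
* ``edge_flip``      — rotate the diagonal of the quad formed by two
  adjacent triangles (connectivity change, vertex count fixed);
* ``divide_face``    — insert a vertex at a face centroid, splitting the
  face in three (refinement);
* ``merge_vertex``   — remove a free vertex and retriangulate (coarsening,
  inverse of division);
* ``resize_box``     — change one bounding-box dimension (a, b, c, gamma),
  enabled for multi-objective studies.

Rules are pure: they return new states and never mutate their input, so a
rejected candidate cannot corrupt the current solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    ExhaustedRetriesError,
    FlipBlockedError,
    MeshInvalidError,
    PreservedGeometryError,
    SpatialConstraintError,
)
from .mesh import (
    BASE_RISE_NM,
    DesignState,
    Edge,
    ExcludedRegion,
    canonical_face,
    make_edge,
    validate_mesh,
)

ALL_RULES = ("extend_vertex", "edge_flip", "divide_face", "merge_vertex", "resize_box")


@dataclass(frozen=True)
class RuleSet:
    """Enabled grammar rules, their selection weights and parameter ranges."""

    enabled: tuple[str, ...] = ("extend_vertex", "edge_flip", "divide_face", "merge_vertex")
    weights: dict[str, float] = field(default_factory=dict)
    k_min: int = 1
    k_max: int = 20
    allow_box_moves: bool = False
    box_step: float = 1.0          # nm step for a/b/c moves
    gamma_step: float = 2.0        # degree step for gamma moves
    box_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "a": (10.0, 100.0),
            "b": (10.0, 100.0),
            "c": (10.0, 100.0),
            "gamma": (45.0, 135.0),
        }
    )

    def __post_init__(self):
        unknown = set(self.enabled) - set(ALL_RULES)
        if unknown:
            raise ValueError(f"unknown rules: {sorted(unknown)}")
        for name, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"rule weight for {name!r} must be positive")
        if self.allow_box_moves and "resize_box" not in self.enabled:
            object.__setattr__(self, "enabled", self.enabled + ("resize_box",))
        if not self.allow_box_moves and "resize_box" in self.enabled:
            object.__setattr__(self, "allow_box_moves", True)

    def probabilities(self) -> tuple[tuple[str, ...], np.ndarray]:
        names = self.enabled
        w = np.array([self.weights.get(n, 1.0) for n in names], dtype=float)
        return names, w / w.sum()

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one rule name according to the normalised weights."""
        names, probs = self.probabilities()
        return names[rng.choice(len(names), p=probs)]


def extend_vertex(
    state: DesignState, vertex_id: int, direction: Sequence[float], k: int
) -> DesignState:
    """Displace a vertex by ``k`` base-pair rises (k * 0.34 nm) along ``direction``."""
    if vertex_id not in state.positions:
        raise KeyError(f"no vertex {vertex_id}")
    if vertex_id in state.preserved_vertices:
        raise PreservedGeometryError(f"vertex {vertex_id} is preserved and cannot move")
    if k == 0:
        return state
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("direction must be a nonzero vector")
    new_pos = state.position(vertex_id) + (k * BASE_RISE_NM / norm) * d
    positions = dict(state.positions)
    positions[vertex_id] = tuple(float(x) for x in new_pos)
    out = state.evolve(positions=positions)
    # the move must not flatten any incident face
    for f in out.faces_of_vertex(vertex_id):
        pa, pb, pc = (positions[v] for v in f)
        u0, u1, u2 = pb[0] - pa[0], pb[1] - pa[1], pb[2] - pa[2]
        v0, v1, v2 = pc[0] - pa[0], pc[1] - pa[1], pc[2] - pa[2]
        cx, cy, cz = u1 * v2 - u2 * v1, u2 * v0 - u0 * v2, u0 * v1 - u1 * v0
        if cx * cx + cy * cy + cz * cz < 1e-9:
            raise MeshInvalidError(f"extension degenerates face {f}")
    return out


def edge_flip(state: DesignState, edge: Edge) -> DesignState:
    """Replace the shared edge of two adjacent triangles by the opposite diagonal."""
    edge = make_edge(*edge)
    if edge in state.preserved_edges:
        raise PreservedGeometryError(f"edge {edge} is preserved and cannot be flipped")
    star = state.faces_of_edge(edge)
    if len(star) != 2:
        raise MeshInvalidError(f"edge {edge} borders {len(star)} faces")
    u, v = edge
    c = d = None
    for f in star:
        # directed edge u->v in this face means the face lies on one side
        for j in range(3):
            if f[j] == u and f[(j + 1) % 3] == v:
                c = f[(j + 2) % 3]
            elif f[j] == v and f[(j + 1) % 3] == u:
                d = f[(j + 2) % 3]
    if c is None or d is None:
        raise MeshInvalidError(f"faces around {edge} are inconsistently oriented")
    new_edge = make_edge(c, d)
    if new_edge in state.edges:
        raise FlipBlockedError(f"opposite diagonal {new_edge} already exists")
    f1 = canonical_face((u, d, c))
    f2 = canonical_face((d, v, c))
    faces = set(state.faces)
    for f in star:
        faces.discard(f)
    faces.update((f1, f2))
    edges = set(state.edges)
    edges.discard(edge)
    edges.add(new_edge)
    out = state.evolve(edges=frozenset(edges), faces=frozenset(faces))
    report = validate_mesh(out)
    if not report.valid:
        raise FlipBlockedError(f"flip of {edge} degenerates the mesh: {report.violations[0]}")
    return out


def divide_face(
    state: DesignState,
    face: tuple[int, int, int],
    excluded: Sequence[ExcludedRegion] = (),
) -> DesignState:
    """Split a face into three by inserting a vertex at its centroid."""
    face = canonical_face(tuple(face))
    if face not in state.faces:
        raise KeyError(f"no face {face}")
    a, b, c = (state.position(v) for v in face)
    centroid = (a + b + c) / 3.0
    for region in excluded:
        if region.contains_point(centroid):
            raise SpatialConstraintError("face centroid falls inside an excluded region")
    new_id = state.next_vertex_id()
    positions = dict(state.positions)
    positions[new_id] = tuple(float(x) for x in centroid)
    i, j, k = face
    faces = set(state.faces)
    faces.discard(face)
    faces.update(
        canonical_face(f) for f in ((i, j, new_id), (j, k, new_id), (k, i, new_id))
    )
    edges = set(state.edges)
    edges.update(make_edge(v, new_id) for v in face)
    return state.evolve(
        positions=positions, edges=frozenset(edges), faces=frozenset(faces)
    )


def merge_vertex(
    state: DesignState, vertex_id: int, collapse_target: int | None = None
) -> DesignState:
    """Remove a free vertex, retriangulating the hole it leaves.

    A degree-3 vertex is removed outright (its link becomes a single face,
    the exact inverse of ``divide_face``).  For higher degree a collapse
    target — a neighbouring vertex the removed vertex merges into — must be
    given.
    """
    if vertex_id not in state.positions:
        raise KeyError(f"no vertex {vertex_id}")
    if vertex_id in state.preserved_vertices:
        raise PreservedGeometryError(f"vertex {vertex_id} is preserved and cannot be removed")
    incident = [e for e in state.edges if vertex_id in e]
    for e in incident:
        if e in state.preserved_edges:
            raise PreservedGeometryError(f"edge {e} is preserved and cannot be removed")
    star = state.faces_of_vertex(vertex_id)
    degree = len(incident)

    positions = dict(state.positions)
    del positions[vertex_id]
    edges = set(state.edges) - set(incident)
    faces = set(state.faces) - set(star)

    if degree == 3 and collapse_target is None:
        # link cycle of the removed vertex becomes the patch face
        link: dict[int, int] = {}
        for f in star:
            i = f.index(vertex_id)
            link[f[(i + 1) % 3]] = f[(i + 2) % 3]
        start = next(iter(link))
        cycle = (start, link[start], link[link[start]])
        faces.add(canonical_face(cycle))
    else:
        if collapse_target is None:
            raise MeshInvalidError(
                f"vertex {vertex_id} has degree {degree}; a collapse target is required"
            )
        if make_edge(vertex_id, collapse_target) not in state.edges:
            raise MeshInvalidError(
                f"collapse target {collapse_target} is not adjacent to {vertex_id}"
            )
        for f in star:
            if collapse_target in f:
                continue  # face vanishes in the collapse
            newf = tuple(collapse_target if v == vertex_id else v for v in f)
            newf = canonical_face(newf)
            if newf in faces:
                raise MeshInvalidError("collapse would duplicate a face")
            faces.add(newf)
        for e in incident:
            other = e[0] if e[1] == vertex_id else e[1]
            if other != collapse_target:
                edges.add(make_edge(other, collapse_target))

    out = state.evolve(positions=positions, edges=frozenset(edges), faces=frozenset(faces))
    report = validate_mesh(out)
    if not report.valid:
        raise MeshInvalidError(
            f"removing vertex {vertex_id} breaks the mesh: {report.violations[0]}"
        )
    return out


def resize_box(
    state: DesignState,
    dimension: str,
    delta: float,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> DesignState:
    """Change one bounding-box dimension; all vertices must stay inside."""
    current = getattr(state.box, dimension)
    value = current + delta
    if bounds is not None and dimension in bounds:
        lo, hi = bounds[dimension]
        if not lo <= value <= hi:
            raise SpatialConstraintError(
                f"box dimension {dimension}={value:.3f} outside bounds [{lo}, {hi}]"
            )
    new_box = state.box.with_dimension(dimension, value)  # validates positivity/angle
    out = state.evolve(box=new_box)
    _, pts = out.vertex_array()
    if len(pts) and not bool(np.all(new_box.contains(pts))):
        raise SpatialConstraintError(
            f"shrinking {dimension} to {value:.3f} would expel a vertex from the box"
        )
    return out


class RuleApplication:
    """Outcome of one random rule draw: the candidate and what produced it."""

    __slots__ = ("state", "rule", "attempts")

    def __init__(self, state: DesignState, rule: str, attempts: int):
        self.state = state
        self.rule = rule
        self.attempts = attempts


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _draw_candidate(
    state: DesignState, rule: str, ruleset: RuleSet, rng: np.random.Generator, k_max: int
) -> DesignState:
    """Apply ``rule`` with randomly drawn parameters; may raise rule errors."""
    if rule == "extend_vertex":
        free = sorted(set(state.positions) - set(state.preserved_vertices))
        if not free:
            raise MeshInvalidError("no movable vertex")
        vid = free[rng.integers(len(free))]
        k = int(rng.integers(ruleset.k_min, max(k_max, ruleset.k_min) + 1))
        return extend_vertex(state, vid, _random_unit_vector(rng), k)
    if rule == "edge_flip":
        flippable = [e for e in state.sorted_edges() if e not in state.preserved_edges]
        if not flippable:
            raise MeshInvalidError("no flippable edge")
        return edge_flip(state, flippable[rng.integers(len(flippable))])
    if rule == "divide_face":
        faces = sorted(state.faces)
        return divide_face(state, faces[rng.integers(len(faces))])
    if rule == "merge_vertex":
        free = sorted(set(state.positions) - set(state.preserved_vertices))
        if not free:
            raise MeshInvalidError("no removable vertex")
        vid = free[rng.integers(len(free))]
        if state.vertex_degree(vid) == 3:
            return merge_vertex(state, vid)
        nbrs = sorted(state.neighbors(vid))
        return merge_vertex(state, vid, collapse_target=nbrs[rng.integers(len(nbrs))])
    if rule == "resize_box":
        dim = ("a", "b", "c", "gamma")[rng.integers(4)]
        step = ruleset.gamma_step if dim == "gamma" else ruleset.box_step
        delta = step if rng.random() < 0.5 else -step
        return resize_box(state, dim, delta, bounds=ruleset.box_bounds)
    raise ValueError(f"unknown rule {rule!r}")


def apply_random_rule(
    state: DesignState,
    ruleset: RuleSet,
    constraints,
    rng: np.random.Generator,
    max_retries: int = 25,
    k_max: int | None = None,
) -> RuleApplication:
    """Draw rules at random until one yields a feasible candidate.

    Rule choice, rule parameters and hence the candidate are fully
    determined by ``rng``.  Raises :class:`ExhaustedRetriesError` after
    ``max_retries`` infeasible draws; the optimiser records a null move.
    """
    from .constraints import is_feasible

    eff_k_max = ruleset.k_max if k_max is None else max(ruleset.k_min, k_max)
    for attempt in range(1, max_retries + 1):
        rule = ruleset.sample(rng)
        try:
            candidate = _draw_candidate(state, rule, ruleset, rng, eff_k_max)
        except (
            PreservedGeometryError,
            MeshInvalidError,
            FlipBlockedError,
            SpatialConstraintError,
        ):
            continue
        if candidate is state:
            continue
        if constraints is None or is_feasible(candidate, constraints).feasible:
            return RuleApplication(candidate, rule, attempt)
    raise ExhaustedRetriesError(
        f"no feasible candidate after {max_retries} rule applications"
    )
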