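"""Graph-backed triangulated mesh model for wireframe DNA origami design.

A candidate nanostructure is a closed, edge-manifold triangle mesh whose
edges will be realised as DNA helix bundles.  Vertices carry Cartesian
positions in nanometres; vertices and edges may be flagged *preserved*,
meaning no generative move may delete or displace them.  Edge lengths are
converted to nucleotide counts through the B-form axial rise of 0.34 nm
per base pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    InfeasibleStartError,
    RegionConflictError,
    TriangulationError,
    ZeroLengthEdgeError,
)

#: axial rise per base pair of B-form DNA, in nm
BASE_RISE_NM = 0.34

_TOL = 1e-9

Edge = tuple[int, int]


def make_edge(u: int, v: int) -> Edge:
    """Canonical (sorted) representation of an undirected edge."""
    if u == v:
        raise ValueError(f"self-loop on vertex {u}")
    return (u, v) if u < v else (v, u)


def canonical_face(face: Sequence[int]) -> tuple[int, int, int]:
    """Rotate a triangle so its smallest vertex id comes first.

    Rotation preserves orientation, so two canonical faces are equal iff
    they are the same oriented triangle.
    """
    a, b, c = face
    if a <= b and a <= c:
        return (a, b, c)
    if b <= a and b <= c:
        return (b, c, a)
    return (c, a, b)


@dataclass(frozen=True)
class BoundingBox:
    """Parallelepiped design envelope.

    Spanned by edge vectors ``a * x_hat``, ``b * (cos g, sin g, 0)`` and
    ``c * z_hat`` from ``origin``, where ``g = gamma`` is the angle between
    the a and b axes in degrees.  Volume is ``a * b * c * sin(gamma)``.
    """

    a: float
    b: float
    c: float
    gamma: float = 90.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("box dimensions must be positive")
        if not 0.0 < self.gamma < 180.0:
            raise ValueError("gamma must lie in (0, 180) degrees")

    @property
    def volume(self) -> float:
        return self.a * self.b * self.c * math.sin(math.radians(self.gamma))

    def basis(self) -> np.ndarray:
        """Columns are the box edge vectors (u, v, w)."""
        g = math.radians(self.gamma)
        return np.array(
            [
                [self.a, self.b * math.cos(g), 0.0],
                [0.0, self.b * math.sin(g), 0.0],
                [0.0, 0.0, self.c],
            ]
        )

    def fractional(self, points: np.ndarray) -> np.ndarray:
        """Coordinates of ``points`` in the box basis (inside iff all in [0,1])."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - np.asarray(self.origin, dtype=float)
        return np.linalg.solve(self.basis(), rel.T).T

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        frac = self.fractional(points)
        return np.all((frac >= -tol) & (frac <= 1.0 + tol), axis=1)

    def with_dimension(self, name: str, value: float) -> "BoundingBox":
        if name not in ("a", "b", "c", "gamma"):
            raise ValueError(f"unknown box dimension {name!r}")
        return replace(self, **{name: value})


@dataclass(frozen=True)
class ExcludedRegion:
    """Axis-aligned convex box that must stay free of DNA material."""

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]

    def __post_init__(self):
        lo = np.asarray(self.min_corner, float)
        hi = np.asarray(self.max_corner, float)
        if not np.all(lo < hi):
            raise ValueError("min_corner must be strictly below max_corner")

    def contains_point(self, p: np.ndarray, shrink: float = 1e-9) -> bool:
        lo = np.asarray(self.min_corner) + shrink
        hi = np.asarray(self.max_corner) - shrink
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def intersects_segment(self, p0: np.ndarray, p1: np.ndarray) -> bool:
        """Exact slab-clipping test of a segment against the open box."""
        lo = np.asarray(self.min_corner, float) + 1e-9
        hi = np.asarray(self.max_corner, float) - 1e-9
        d = np.asarray(p1, float) - np.asarray(p0, float)
        t0, t1 = 0.0, 1.0
        for k in range(3):
            if abs(d[k]) < 1e-15:
                if p0[k] < lo[k] or p0[k] > hi[k]:
                    return False
            else:
                ta = (lo[k] - p0[k]) / d[k]
                tb = (hi[k] - p0[k]) / d[k]
                if ta > tb:
                    ta, tb = tb, ta
                t0 = max(t0, ta)
                t1 = min(t1, tb)
                if t0 >= t1:
                    return False
        return True


@dataclass(frozen=True)
class EdgeTypeSpec:
    """Helix-bundle edge type.

    ``helices_per_edge`` is the number of parallel double helices in the
    bundle; ``scaffold_passes`` how many times the scaffold strand runs
    along the edge (one pass per helix for DAEDALUS-style routings);
    ``bundle_diameter`` the effective cylinder diameter in nm used by the
    porosity model; ``min_edge_nt`` the shortest per-helix edge, in base
    pairs, that downstream sequence-design tools accept.
    """

    name: str
    helices_per_edge: int
    bundle_diameter: float
    min_edge_nt: int = 31
    scaffold_passes: int | None = None

    def __post_init__(self):
        if self.helices_per_edge < 1:
            raise ValueError("helices_per_edge must be positive")
        if self.bundle_diameter <= 0:
            raise ValueError("bundle_diameter must be positive")
        if self.scaffold_passes is None:
            object.__setattr__(self, "scaffold_passes", self.helices_per_edge)


#: built-in edge types: duplex (1HB), two-helix (2HB) and six-helix (6HB)
#: bundles with effective cylinder diameters of 2, 4 and 6 nm.
EDGE_TYPES: dict[str, EdgeTypeSpec] = {
    "1HB": EdgeTypeSpec("1HB", 1, 2.0),
    "2HB": EdgeTypeSpec("2HB", 2, 4.0),
    "6HB": EdgeTypeSpec("6HB", 6, 6.0),
}


@dataclass(frozen=True)
class DesignState:
    """Immutable snapshot of a candidate design (vertices, edges, faces, box).

    Grammar rules never mutate a state; they return modified copies, so a
    rejected candidate can simply be dropped.
    """

    positions: dict[int, tuple[float, float, float]]
    edges: frozenset[Edge]
    faces: frozenset[tuple[int, int, int]]
    box: BoundingBox
    edge_type: EdgeTypeSpec
    preserved_vertices: frozenset[int] = frozenset()
    preserved_edges: frozenset[Edge] = frozenset()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def build(
        positions: dict[int, Sequence[float]],
        edges: Iterable[Sequence[int]],
        faces: Iterable[Sequence[int]],
        box: BoundingBox,
        edge_type: EdgeTypeSpec,
        preserved_vertices: Iterable[int] = (),
        preserved_edges: Iterable[Sequence[int]] = (),
    ) -> "DesignState":
        pos = {int(k): tuple(float(x) for x in v) for k, v in positions.items()}
        return DesignState(
            positions=pos,
            edges=frozenset(make_edge(*e) for e in edges),
            faces=frozenset(canonical_face(tuple(f)) for f in faces),
            box=box,
            edge_type=edge_type,
            preserved_vertices=frozenset(int(v) for v in preserved_vertices),
            preserved_edges=frozenset(make_edge(*e) for e in preserved_edges),
        )

    def evolve(self, **changes) -> "DesignState":
        return replace(self, **changes)

    # -- queries --------------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def position(self, vid: int) -> np.ndarray:
        return np.asarray(self.positions[vid], dtype=float)

    def next_vertex_id(self) -> int:
        return max(self.positions) + 1 if self.positions else 0

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def edge_endpoints(self) -> tuple[list[Edge], np.ndarray, np.ndarray]:
        """Edge list with (n,3) endpoint arrays, in sorted edge order.

        Cached: the state is immutable, so the arrays are built once.
        """
        cached = getattr(self, "_endpoint_cache", None)
        if cached is None:
            edges = self.sorted_edges()
            p = np.array([self.positions[u] for u, _ in edges], dtype=float)
            q = np.array([self.positions[v] for _, v in edges], dtype=float)
            cached = (edges, p, q)
            object.__setattr__(self, "_endpoint_cache", cached)
        return cached

    def edge_lengths(self) -> np.ndarray:
        cached = getattr(self, "_length_cache", None)
        if cached is None:
            _, p, q = self.edge_endpoints()
            cached = np.linalg.norm(q - p, axis=1) if len(p) else np.empty(0)
            object.__setattr__(self, "_length_cache", cached)
        return cached

    def edge_length(self, edge: Edge) -> float:
        u, v = edge
        return float(np.linalg.norm(self.position(u) - self.position(v)))

    def vertex_degree(self, vid: int) -> int:
        return sum(1 for e in self.edges if vid in e)

    def neighbors(self, vid: int) -> set[int]:
        out: set[int] = set()
        for u, v in self.edges:
            if u == vid:
                out.add(v)
            elif v == vid:
                out.add(u)
        return out

    def faces_of_edge(self, edge: Edge) -> list[tuple[int, int, int]]:
        u, v = edge
        return [f for f in self.faces if u in f and v in f]

    def faces_of_vertex(self, vid: int) -> list[tuple[int, int, int]]:
        return [f for f in self.faces if vid in f]

    def vertex_array(self) -> tuple[list[int], np.ndarray]:
        ids = sorted(self.positions)
        return ids, np.array([self.positions[i] for i in ids], dtype=float)


class MeshReport(NamedTuple):
    valid: bool
    violations: tuple[str, ...]


def validate_mesh(state: DesignState) -> MeshReport:
    """Check that a state is a closed, edge-manifold, all-triangle surface.

    Returns a report rather than raising: grammar rules use it to vet their
    own output, and callers may want the full violation list.
    """
    violations: list[str] = []
    positions = state.positions
    edge_face_count: dict[Edge, int] = {}
    stars: dict[int, list[tuple[int, int, int]]] = {v: [] for v in positions}
    seen_vertex_sets: set[frozenset[int]] = set()
    for f in state.faces:
        a, b, c = f
        if a == b or b == c or a == c:
            violations.append(f"degenerate face (repeated vertex): {f}")
            continue
        vset = frozenset(f)
        if vset in seen_vertex_sets:
            # two faces over the same vertices (a zero-volume "pillow")
            violations.append(f"duplicate face over vertices {sorted(vset)}")
        seen_vertex_sets.add(vset)
        missing = False
        for vid in f:
            if vid in stars:
                stars[vid].append(f)
            else:
                violations.append(f"face {f} references missing vertex {vid}")
                missing = True
        for e in ((a, b) if a < b else (b, a), (b, c) if b < c else (c, b),
                  (a, c) if a < c else (c, a)):
            edge_face_count[e] = edge_face_count.get(e, 0) + 1
        if missing:
            continue
        # zero-area check with plain tuple arithmetic (hot path)
        pa, pb, pc = positions[a], positions[b], positions[c]
        u0, u1, u2 = pb[0] - pa[0], pb[1] - pa[1], pb[2] - pa[2]
        v0, v1, v2 = pc[0] - pa[0], pc[1] - pa[1], pc[2] - pa[2]
        cx, cy, cz = u1 * v2 - u2 * v1, u2 * v0 - u0 * v2, u0 * v1 - u1 * v0
        if cx * cx + cy * cy + cz * cz < _TOL:
            violations.append(f"zero-area face {f}")
    for e in state.edges:
        u, v = e
        if u not in positions or v not in positions:
            violations.append(f"edge {e} references missing vertex")
    # closed + edge-manifold: every edge borders exactly two faces
    for e, n in edge_face_count.items():
        if e not in state.edges:
            violations.append(f"face edge {e} missing from edge set")
        if n != 2:
            violations.append(f"edge {e} borders {n} faces (expected 2)")
    for e in state.edges:
        if e not in edge_face_count:
            violations.append(f"edge {e} borders 0 faces (expected 2)")
    # vertex-manifoldness: faces around each vertex form a single fan
    if not violations:
        for vid, star in stars.items():
            if not star:
                violations.append(f"isolated vertex {vid}")
            elif not _star_is_single_cycle(vid, star):
                violations.append(f"non-manifold vertex {vid}")
    valid = not violations
    return MeshReport(valid, tuple(violations))


def _star_is_single_cycle(vid: int, star: list[tuple[int, int, int]]) -> bool:
    """True iff the link of ``vid`` is one closed cycle (disc neighbourhood)."""
    link: dict[int, int] = {}
    for f in star:
        i = f.index(vid)
        a, b = f[(i + 1) % 3], f[(i + 2) % 3]
        if a in link:
            return False
        link[a] = b
    start = next(iter(link))
    cur, steps = link[start], 1
    while cur != start:
        if cur not in link or steps > len(link):
            return False
        cur = link[cur]
        steps += 1
    return steps == len(star)


class EdgeNucleotides(NamedTuple):
    bp_per_helix: int
    scaffold_nt: int


def edge_length_nt(
    edge: Edge, state: DesignState, spec: EdgeTypeSpec | None = None
) -> EdgeNucleotides:
    """Nucleotide content of one edge under the 0.34 nm/bp rise model.

    Per-helix base pairs are the edge length divided by the rise, rounded
    half-to-even; the scaffold contribution multiplies by the number of
    scaffold passes through the bundle.
    """
    spec = spec or state.edge_type
    length = state.edge_length(edge)
    if length < _TOL:
        raise ZeroLengthEdgeError(f"edge {edge} has zero length")
    bp = int(np.rint(length / BASE_RISE_NM))
    return EdgeNucleotides(bp, spec.scaffold_passes * bp)


def estimate_scaffold_nt(state: DesignState, vertex_correction: int = 0) -> int:
    """Total scaffold nucleotides demanded by the design.

    Sum over edges of ``scaffold_passes * round(length / 0.34)``, plus an
    optional additive per-vertex correction (default 0) for routings that
    spend scaffold at vertices.
    """
    lengths = state.edge_lengths()
    bp = np.rint(lengths / BASE_RISE_NM).astype(int)
    total = int(bp.sum()) * state.edge_type.scaffold_passes
    return total + vertex_correction * state.n_vertices


def segment_pair_distances(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Minimum distances between segment pairs (vectorised, clamped form)."""
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > _TOL, (b * f - c * e) / np.where(denom > _TOL, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    # recompute t for clamped s, then clamp and recompute s
    t = np.where(e > _TOL, (b * s + f) / np.where(e > _TOL, e, 1.0), 0.0)
    t_cl = np.clip(t, 0.0, 1.0)
    s = np.where(
        (t_cl != t),
        np.clip(np.where(a > _TOL, (b * t_cl - c) / np.where(a > _TOL, a, 1.0), 0.0), 0.0, 1.0),
        s,
    )
    closest1 = p1 + s[:, None] * d1
    closest2 = q1 + t_cl[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1)


def min_nonadjacent_edge_distance(state: DesignState) -> float:
    """Minimum distance between any two edges that share no vertex.

    This is the quantity a repulsion constraint bounds from below so that
    helix bundles are not packed against each other.  Returns ``inf`` when
    every edge pair is adjacent.
    """
    edges, p, q = state.edge_endpoints()
    n = len(edges)
    if n < 2:
        return math.inf
    ii, jj = np.triu_indices(n, k=1)
    ends = np.array(edges)
    share = (
        (ends[ii, 0] == ends[jj, 0])
        | (ends[ii, 0] == ends[jj, 1])
        | (ends[ii, 1] == ends[jj, 0])
        | (ends[ii, 1] == ends[jj, 1])
    )
    keep = ~share
    if not keep.any():
        return math.inf
    d = segment_pair_distances(p[ii[keep]], q[ii[keep]], p[jj[keep]], q[jj[keep]])
    return float(d.min())


def _hull_faces(points: np.ndarray) -> list[tuple[int, int, int]]:
    """Outward-oriented triangular faces of the convex hull of ``points``."""
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise TriangulationError(f"preserved vertices cannot be triangulated: {exc}") from exc
    if len(hull.vertices) != len(points):
        missing = sorted(set(range(len(points))) - set(hull.vertices))
        raise TriangulationError(
            f"preserved vertices {missing} are interior to the convex hull; "
            "they cannot appear on a closed triangulated surface"
        )
    centroid = points.mean(axis=0)
    faces = []
    for simplex, eq in zip(hull.simplices, hull.equations):
        i, j, k = (int(x) for x in simplex)
        normal = np.cross(points[j] - points[i], points[k] - points[i])
        if np.dot(normal, eq[:3]) < 0:
            j, k = k, j
        faces.append(canonical_face((i, j, k)))
    return faces


def initialize_design(
    preserved_vertices: Sequence[Sequence[float]],
    preserved_edges: Sequence[tuple[Sequence[float], Sequence[float]]] = (),
    excluded: Sequence[ExcludedRegion] = (),
    box: BoundingBox | None = None,
    edge_type: EdgeTypeSpec | None = None,
    constraints=None,
) -> DesignState:
    """Build the initial design s_1 by triangulating the preserved geometry.

    The initial surface is the convex hull of the preserved vertices — the
    canonical minimal closed triangulation.  Preserved edges must come out
    as hull edges; a preserved chord interior to the hull is rejected.

    Raises
    ------
    TriangulationError
        Fewer than 4 points, coplanar points, interior points, or a
        preserved edge that the hull triangulation does not contain.
    RegionConflictError
        Preserved geometry lies inside an excluded region.
    InfeasibleStartError
        The triangulated state violates containment, excluded regions, or
        the supplied constraint set; the generative process cannot begin.
    """
    pts = np.asarray(preserved_vertices, dtype=float)
    extra = []
    for a, b in preserved_edges:
        for p in (a, b):
            if not any(np.allclose(p, q, atol=1e-9) for q in pts) and not any(
                np.allclose(p, q, atol=1e-9) for q in extra
            ):
                extra.append(np.asarray(p, dtype=float))
    if extra:
        pts = np.vstack([pts, extra]) if len(pts) else np.array(extra)
    if len(pts) < 4:
        raise TriangulationError("need at least 4 non-coplanar preserved vertices")
    if not np.all(np.isfinite(pts)):
        raise TriangulationError("preserved vertex positions must be finite")

    if box is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        box = BoundingBox(*(float(max(s, 1.0)) for s in span), origin=tuple(pts.min(axis=0)))
    if edge_type is None:
        edge_type = EDGE_TYPES["2HB"]

    if not np.all(box.contains(pts)):
        raise InfeasibleStartError("a preserved vertex lies outside the bounding box")
    for region in excluded:
        for p in pts:
            if region.contains_point(p):
                raise RegionConflictError(f"preserved vertex {p.tolist()} inside excluded region")

    faces = _hull_faces(pts)
    edges = set()
    for f in faces:
        for i in range(3):
            edges.add(make_edge(f[i], f[(i + 1) % 3]))

    def _vertex_index(p) -> int:
        for idx, q in enumerate(pts):
            if np.allclose(p, q, atol=1e-9):
                return idx
        raise TriangulationError(f"preserved edge endpoint {p} is not a preserved vertex")

    pres_edges = set()
    for a, b in preserved_edges:
        e = make_edge(_vertex_index(a), _vertex_index(b))
        if e not in edges:
            raise TriangulationError(
                f"preserved edge {e} is not an edge of the convex-hull triangulation"
            )
        pres_edges.add(e)

    state = DesignState.build(
        positions={i: pts[i] for i in range(len(pts))},
        edges=edges,
        faces=faces,
        box=box,
        edge_type=edge_type,
        preserved_vertices=range(len(pts)),
        preserved_edges=pres_edges,
    )
    report = validate_mesh(state)
    if not report.valid:
        raise TriangulationError(f"triangulated start is not a valid mesh: {report.violations}")

    # excluded regions must not be crossed by any starting edge
    _, p, q = state.edge_endpoints()
    for region in excluded:
        for a, b in zip(p, q):
            if region.intersects_segment(a, b):
                raise InfeasibleStartError(
                    "a starting edge crosses an excluded region; the generative "
                    "process cannot begin"
                )
    if constraints is not None:
        from .constraints import is_feasible

        rep = is_feasible(state, constraints)
        if not rep.feasible:
            raise InfeasibleStartError(
                f"triangulated start violates constraints: {rep.violations}"
            )
    return state
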