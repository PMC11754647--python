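"""Mesh model: initialization, validity checking, nucleotide accounting,
and inter-edge distances."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import wireforge as wf
from wireforge.errors import (
    InfeasibleStartError,
    RegionConflictError,
    TriangulationError,
    ZeroLengthEdgeError,
)
from wireforge.mesh import segment_pair_distances

from conftest import UNIT_TETRA, random_feasible_start


def open_state(points, edges, edge_type="1HB", box=None):
    """Raw (not necessarily closed) state for per-edge unit checks."""
    return wf.DesignState.build(
        positions={i: p for i, p in enumerate(points)},
        edges=edges,
        faces=[],
        box=box or wf.BoundingBox(100, 100, 100, origin=(-50, -50, -50)),
        edge_type=wf.EDGE_TYPES[edge_type],
    )


class TestInitialize:
    def test_tetrahedron_counts(self, tetra):
        assert (tetra.n_vertices, tetra.n_edges, tetra.n_faces) == (4, 6, 4)
        assert tetra.euler_characteristic() == 2
        assert wf.validate_mesh(tetra).valid
        assert tetra.preserved_vertices == frozenset(range(4))

    def test_midface_octahedron_matches_convex_hull_oracle(self, octa):
        pts = np.array(wf.fixture_parallelepiped_midfaces(50, 50, 50))
        hull = ConvexHull(pts)
        n_faces = len(hull.simplices)
        n_edges = len({tuple(sorted((s[i], s[(i + 1) % 3]))) for s in hull.simplices
                       for i in range(3)})
        assert (octa.n_vertices, octa.n_edges, octa.n_faces) == (6, n_edges, n_faces)
        assert (octa.n_vertices, octa.n_edges, octa.n_faces) == (6, 12, 8)
        assert wf.validate_mesh(octa).valid

    def test_coplanar_points_rejected(self):
        with pytest.raises(TriangulationError):
            wf.initialize_design([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(TriangulationError):
            wf.initialize_design([(0, 0, 0), (1, 0, 0), (0, 1, 0)])

    def test_interior_point_rejected(self):
        pts = UNIT_TETRA + [(0.1, 0.1, 0.1)]
        with pytest.raises(TriangulationError, match="interior"):
            wf.initialize_design(pts)

    def test_preserved_edge_on_hull_is_flagged(self):
        state = wf.initialize_design(
            UNIT_TETRA, preserved_edges=[((0, 0, 0), (1, 0, 0))]
        )
        assert (0, 1) in state.preserved_edges

    def test_preserved_vertex_outside_box_rejected(self):
        with pytest.raises(InfeasibleStartError):
            wf.initialize_design(UNIT_TETRA, box=wf.BoundingBox(0.5, 2, 2))

    def test_preserved_vertex_in_excluded_region_rejected(self):
        region = wf.ExcludedRegion((-0.1, -0.1, -0.1), (0.2, 0.2, 0.2))
        with pytest.raises(RegionConflictError):
            wf.initialize_design(UNIT_TETRA, excluded=[region])

    def test_starting_edge_through_excluded_region_rejected(self):
        # a cube edge passes straight through a centred excluded box
        region = wf.ExcludedRegion((20, -1, -1), (30, 1, 1))
        with pytest.raises(InfeasibleStartError):
            wf.initialize_design(
                wf.fixture_cube_corners(50), excluded=[region],
                box=wf.BoundingBox(50, 50, 50),
            )


class TestValidateMesh:
    def test_tetrahedron_valid(self, tetra):
        assert wf.validate_mesh(tetra) == (True, ())

    def test_open_mesh_reports_boundary_edges(self, tetra):
        broken = tetra.evolve(faces=frozenset(list(tetra.faces)[1:]))
        report = wf.validate_mesh(broken)
        assert not report.valid
        assert sum("borders 1 faces" in v for v in report.violations) == 3

    def test_two_tetrahedra_glued_at_vertex_nonmanifold(self):
        # incidence-count oracle: the shared vertex has two disjoint face fans
        pts = UNIT_TETRA + [(-1.0, 0.0, 0.0), (0.0, -1.0, 0.0), (0.0, 0.0, -1.0)]
        t1 = wf.initialize_design(UNIT_TETRA)
        t2 = wf.initialize_design([pts[0], pts[4], pts[5], pts[6]])
        remap = {0: 0, 1: 4, 2: 5, 3: 6}
        state = wf.DesignState.build(
            positions={i: p for i, p in enumerate(pts)},
            edges=list(t1.edges) + [(remap[u], remap[v]) for u, v in t2.edges],
            faces=list(t1.faces) + [tuple(remap[v] for v in f) for f in t2.faces],
            box=wf.BoundingBox(4, 4, 4, origin=(-2, -2, -2)),
            edge_type=wf.EDGE_TYPES["2HB"],
        )
        report = wf.validate_mesh(state)
        assert not report.valid
        assert any("non-manifold vertex 0" in v for v in report.violations)

    def test_duplicate_face_breaks_edge_count(self, tetra):
        f = next(iter(tetra.faces))
        flipped = (f[0], f[2], f[1])
        bad = tetra.evolve(faces=frozenset(set(tetra.faces) | {flipped}))
        assert not wf.validate_mesh(bad).valid


class TestNucleotideAccounting:
    @pytest.mark.parametrize(
        "length,etype,bp,nt",
        [
            (3.4, "2HB", 10, 20),
            (0.34, "1HB", 1, 1),
            (13.6, "6HB", 40, 240),
        ],
    )
    def test_edge_length_nt(self, length, etype, bp, nt):
        state = open_state([(0, 0, 0), (length, 0, 0)], [(0, 1)], etype)
        result = wf.edge_length_nt((0, 1), state)
        assert result.bp_per_helix == bp
        assert result.scaffold_nt == nt

    def test_zero_length_edge_raises(self):
        state = open_state([(0, 0, 0), (0, 0, 0)], [(0, 1)])
        with pytest.raises(ZeroLengthEdgeError):
            wf.edge_length_nt((0, 1), state)

    def test_regular_tetrahedron_scaffold_estimate(self):
        # per-edge sum oracle: 6 edges x 2 passes x round(17/0.34) = 600 nt
        a = 17.0
        pts = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], float)
        pts *= a / np.linalg.norm(pts[0] - pts[1])
        state = wf.initialize_design(pts, box=wf.BoundingBox(40, 40, 40, origin=(-20, -20, -20)))
        state = state.evolve(edge_type=wf.EDGE_TYPES["2HB"])
        expected = sum(
            wf.EDGE_TYPES["2HB"].scaffold_passes
            * round(state.edge_length(e) / wf.BASE_RISE_NM)
            for e in state.edges
        )
        assert expected == 600
        assert wf.estimate_scaffold_nt(state) == 600

    def test_single_preserved_edge_open_state(self):
        state = open_state([(0, 0, 0), (3.4, 0, 0)], [(0, 1)], "1HB")
        assert wf.estimate_scaffold_nt(state) == 10

    def test_scaling_doubles_estimate_within_rounding(self, octa):
        doubled = octa.evolve(
            positions={k: tuple(2 * x for x in v) for k, v in octa.positions.items()},
            box=wf.BoundingBox(100, 100, 100),
        )
        base = wf.estimate_scaffold_nt(octa)
        assert abs(wf.estimate_scaffold_nt(doubled) - 2 * base) <= octa.n_edges

    def test_estimate_increases_when_edge_added(self, free_tetra, loose_constraints):
        divided = wf.divide_face(free_tetra, next(iter(free_tetra.faces)))
        assert wf.estimate_scaffold_nt(divided) > wf.estimate_scaffold_nt(free_tetra)

    def test_vertex_correction_term(self, tetra):
        base = wf.estimate_scaffold_nt(tetra)
        assert wf.estimate_scaffold_nt(tetra, vertex_correction=10) == base + 40


def sampled_segment_distance(p1, p2, q1, q2, n=21):
    """Independent oracle: grid search plus bounded convex minimisation.

    The squared distance between points of two segments is a convex
    quadratic in (s, t) over the unit square, so a bounded minimiser
    started from the grid argmin reaches the global minimum.
    """
    from scipy.optimize import minimize

    p1, p2, q1, q2 = (np.asarray(x, float) for x in (p1, p2, q1, q2))
    d1, d2 = p2 - p1, q2 - q1
    s = np.linspace(0.0, 1.0, n)
    P = p1 + s[:, None] * d1
    Q = q1 + s[:, None] * d2
    D = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(D), D.shape)

    def sqdist(x):
        diff = (p1 + x[0] * d1) - (q1 + x[1] * d2)
        return float(diff @ diff)

    res = minimize(sqdist, x0=[s[i], s[j]], bounds=[(0, 1), (0, 1)], method="L-BFGS-B")
    return math.sqrt(min(res.fun, float(D[i, j]) ** 2))


class TestEdgeDistances:
    def test_parallel_offset_segments(self):
        state = open_state(
            [(0, 0, 0), (1, 0, 0), (0, 0, 2), (1, 0, 2)], [(0, 1), (2, 3)]
        )
        assert wf.min_nonadjacent_edge_distance(state) == pytest.approx(2.0)

    def test_crossing_segments(self):
        state = open_state(
            [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0)], [(0, 1), (2, 3)]
        )
        assert wf.min_nonadjacent_edge_distance(state) == pytest.approx(0.0, abs=1e-12)

    def test_regular_tetrahedron_opposite_edges(self):
        pts = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], float)
        pts /= np.linalg.norm(pts[0] - pts[1])  # unit edge length
        state = wf.initialize_design(pts, box=wf.BoundingBox(2, 2, 2, origin=(-1, -1, -1)))
        assert wf.min_nonadjacent_edge_distance(state) == pytest.approx(1 / math.sqrt(2))

    def test_all_pairs_adjacent_gives_infinity(self):
        state = open_state([(0, 0, 0), (1, 0, 0), (0, 1, 0)], [(0, 1), (1, 2), (0, 2)])
        assert wf.min_nonadjacent_edge_distance(state) == math.inf

    def test_matches_sampling_oracle_on_random_meshes(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            state = random_feasible_start(rng)
            edges, p, q = state.edge_endpoints()
            expected = math.inf
            for i in range(len(edges)):
                for j in range(i + 1, len(edges)):
                    if set(edges[i]) & set(edges[j]):
                        continue
                    expected = min(
                        expected, sampled_segment_distance(p[i], q[i], p[j], q[j])
                    )
            got = wf.min_nonadjacent_edge_distance(state)
            assert got == pytest.approx(expected, abs=1e-3)

    def test_vectorised_distances_match_scalar_oracle(self):
        rng = np.random.default_rng(7)
        p1, p2, q1, q2 = (rng.normal(size=(50, 3)) for _ in range(4))
        d = segment_pair_distances(p1, p2, q1, q2)
        for k in range(50):
            assert d[k] == pytest.approx(
                sampled_segment_distance(p1[k], p2[k], q1[k], q2[k]), abs=1e-6
            )
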