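"""Grammar rules: geometric quantisation, topological bookkeeping,
inverses, and the random rule applicator."""

import numpy as np
import pytest

import wireforge as wf
from wireforge.errors import (
    ExhaustedRetriesError,
    FlipBlockedError,
    MeshInvalidError,
    PreservedGeometryError,
    SpatialConstraintError,
)

from conftest import random_feasible_start


class TestExtendVertex:
    def test_zero_steps_is_identity(self, free_tetra):
        assert wf.extend_vertex(free_tetra, 0, (1, 0, 0), 0) is free_tetra

    def test_displacement_is_quantised_to_base_rise(self, free_tetra):
        out = wf.extend_vertex(free_tetra, 0, (1, 0, 0), 10)
        assert out.positions[0] == pytest.approx((3.4, 0.0, 0.0))
        # all other vertices untouched; input state unchanged
        assert free_tetra.positions[0] == (0.0, 0.0, 0.0)
        assert out.positions[1] == free_tetra.positions[1]

    def test_direction_is_normalised(self, free_tetra):
        out = wf.extend_vertex(free_tetra, 0, (0, 0, 5), 1)
        assert out.positions[0] == pytest.approx((0.0, 0.0, 0.34))

    def test_preserved_vertex_blocked(self, tetra):
        with pytest.raises(PreservedGeometryError):
            wf.extend_vertex(tetra, 0, (1, 0, 0), 1)

    def test_degenerating_move_blocked(self):
        # apex drops onto the midpoint of a base edge -> collinear face
        state = wf.initialize_design(
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0.5, 0.0, 0.34)]
        ).evolve(preserved_vertices=frozenset())
        with pytest.raises(MeshInvalidError):
            wf.extend_vertex(state, 3, (0, 0, -1), 1)


class TestEdgeFlip:
    def test_tetrahedron_flip_blocked(self, free_tetra):
        # every opposite diagonal already exists in a tetrahedron
        with pytest.raises(FlipBlockedError):
            wf.edge_flip(free_tetra, (0, 1))

    def test_flip_swaps_diagonal_and_preserves_counts(self, free_octa):
        edge = next(iter(free_octa.edges))
        out = wf.edge_flip(free_octa, edge)
        assert (out.n_vertices, out.n_edges, out.n_faces) == (
            free_octa.n_vertices, free_octa.n_edges, free_octa.n_faces
        )
        assert edge not in out.edges
        assert wf.validate_mesh(out).valid

    def test_flip_is_involution(self, free_octa):
        edge = next(iter(free_octa.edges))
        once = wf.edge_flip(free_octa, edge)
        (new_edge,) = once.edges - free_octa.edges
        twice = wf.edge_flip(once, new_edge)
        assert twice.edges == free_octa.edges
        assert twice.faces == free_octa.faces

    def test_preserved_edge_blocked(self, octa):
        edge = next(iter(octa.edges))
        state = octa.evolve(preserved_edges=frozenset([edge]))
        with pytest.raises(PreservedGeometryError):
            wf.edge_flip(state, edge)


class TestDivideAndMerge:
    def test_divide_counts_and_euler(self, free_tetra):
        out = wf.divide_face(free_tetra, next(iter(free_tetra.faces)))
        assert (out.n_vertices, out.n_edges, out.n_faces) == (5, 9, 6)
        assert out.euler_characteristic() == 2
        assert wf.validate_mesh(out).valid

    def test_divide_places_vertex_at_centroid(self):
        state = wf.initialize_design([(0, 0, 0), (3, 0, 0), (0, 3, 0), (0, 0, 3)])
        state = state.evolve(preserved_vertices=frozenset())
        face = next(f for f in state.faces if set(f) == {0, 1, 2})
        out = wf.divide_face(state, face)
        assert out.positions[out.next_vertex_id() - 1] == pytest.approx((1.0, 1.0, 0.0))

    def test_divide_into_excluded_region_blocked(self, free_tetra):
        region = wf.ExcludedRegion((-1, -1, -1), (2, 2, 2))  # swallows every centroid
        with pytest.raises(SpatialConstraintError):
            wf.divide_face(free_tetra, next(iter(free_tetra.faces)), excluded=[region])

    def test_merge_inverts_divide(self, free_tetra):
        divided = wf.divide_face(free_tetra, next(iter(free_tetra.faces)))
        new_vertex = divided.next_vertex_id() - 1
        merged = wf.merge_vertex(divided, new_vertex)
        assert merged.edges == free_tetra.edges
        assert merged.faces == free_tetra.faces
        assert merged.positions == free_tetra.positions

    def test_merge_preserved_vertex_blocked(self, tetra):
        with pytest.raises(PreservedGeometryError):
            wf.merge_vertex(tetra, 0)

    def test_merge_below_tetrahedron_blocked(self, free_tetra):
        with pytest.raises(MeshInvalidError):
            wf.merge_vertex(free_tetra, 0)

    def test_degree_four_collapse_keeps_manifold(self, free_octa):
        # Euler + manifoldness oracle for the higher-degree collapse path
        target = sorted(free_octa.neighbors(0))[0]
        out = wf.merge_vertex(free_octa, 0, collapse_target=target)
        assert out.n_vertices == free_octa.n_vertices - 1
        assert out.euler_characteristic() == 2
        assert wf.validate_mesh(out).valid


class TestResizeBox:
    def test_grow_a_updates_volume(self, cube_state):
        out = wf.resize_box(cube_state, "a", 1.0)
        assert out.box.volume == pytest.approx(51 * 50 * 50)

    def test_gamma_shear_volume(self):
        assert wf.BoundingBox(50, 50, 50, 60).volume == pytest.approx(
            125000 * np.sin(np.radians(60))
        )
        # an interior mesh survives the shear and sees the new volume
        state = wf.initialize_design(
            [(20, 20, 20), (30, 22, 20), (22, 30, 24), (24, 22, 30)],
            box=wf.BoundingBox(50, 50, 50),
        )
        out = wf.resize_box(state, "gamma", -30.0)
        assert out.box.volume == pytest.approx(125000 * np.sin(np.radians(60)))

    def test_gamma_shear_expelling_vertices_blocked(self, cube_state):
        # the cube corner (50, 0, *) leaves the sheared box
        with pytest.raises(SpatialConstraintError):
            wf.resize_box(cube_state, "gamma", -30.0)

    def test_shrink_below_occupied_coordinate_blocked(self, cube_state):
        with pytest.raises(SpatialConstraintError):
            wf.resize_box(cube_state, "a", -1.0)

    def test_bounds_enforced(self, cube_state):
        with pytest.raises(SpatialConstraintError):
            wf.resize_box(cube_state, "a", 1.0, bounds={"a": (10, 50.5)})


class TestApplyRandomRule:
    def test_fixed_seed_reproduces_candidate(self, octa, loose_constraints):
        rs = wf.RuleSet()
        a = wf.apply_random_rule(octa, rs, loose_constraints, np.random.default_rng(5))
        b = wf.apply_random_rule(octa, rs, loose_constraints, np.random.default_rng(5))
        assert a.rule == b.rule
        assert a.state.positions == b.state.positions
        assert a.state.edges == b.state.edges

    def test_candidate_differs_and_is_feasible(self, octa, loose_constraints):
        rng = np.random.default_rng(11)
        for _ in range(50):
            app = wf.apply_random_rule(octa, wf.RuleSet(), loose_constraints, rng)
            assert app.state is not octa
            assert wf.validate_mesh(app.state).valid
            assert wf.is_feasible(app.state, loose_constraints).feasible

    def test_rule_draw_frequencies_match_weights(self):
        # multinomial oracle: empirical frequencies within 3 sigma of weights
        weights = {"extend_vertex": 1.0, "edge_flip": 2.0, "divide_face": 3.0,
                   "merge_vertex": 4.0}
        rs = wf.RuleSet(weights=weights)
        rng = np.random.default_rng(123)
        n = 10_000
        counts = {name: 0 for name in rs.enabled}
        for _ in range(n):
            counts[rs.sample(rng)] += 1
        total_w = sum(weights.values())
        for name, w in weights.items():
            p = w / total_w
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[name] - n * p) < 3 * sigma

    def test_impossible_constraints_exhaust_retries(self, octa):
        impossible = wf.ConstraintSet(scaffold_budget=1)
        with pytest.raises(ExhaustedRetriesError):
            wf.apply_random_rule(octa, wf.RuleSet(), impossible,
                                 np.random.default_rng(0), max_retries=5)

    def test_fuzzed_applications_keep_invariants(self, loose_constraints):
        # small-scale fuzz; the full 10k-application sweep runs in the
        # acceptance suite
        rng = np.random.default_rng(99)
        state = random_feasible_start(rng)
        pres_v = state.preserved_vertices
        pres_pos = {v: state.positions[v] for v in pres_v}
        for _ in range(300):
            try:
                app = wf.apply_random_rule(state, wf.RuleSet(), loose_constraints, rng)
            except ExhaustedRetriesError:
                continue
            state = app.state
            assert wf.validate_mesh(state).valid
            assert pres_v <= state.preserved_vertices
            assert all(state.positions[v] == pres_pos[v] for v in pres_v)
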