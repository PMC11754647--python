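import numpy as np
import pytest
from hypothesis import settings

import wireforge as wf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


UNIT_TETRA = [(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]


@pytest.fixture
def tetra():
    """Unit tetrahedron with all four corners preserved."""
    return wf.initialize_design(UNIT_TETRA)


@pytest.fixture
def free_tetra(tetra):
    """Same tetrahedron with the preservation flags cleared, so grammar
    rules can act on every vertex and edge."""
    return tetra.evolve(preserved_vertices=frozenset(), preserved_edges=frozenset())


@pytest.fixture
def octa():
    """Octahedral start from the six face centres of a 50 nm cube."""
    pts = wf.fixture_parallelepiped_midfaces(50, 50, 50)
    return wf.initialize_design(pts, box=wf.BoundingBox(50, 50, 50),
                                edge_type=wf.EDGE_TYPES["2HB"])


@pytest.fixture
def free_octa(octa):
    return octa.evolve(preserved_vertices=frozenset(), preserved_edges=frozenset())


@pytest.fixture
def cube_state():
    """Cube-corner start of the 50 nm single-objective porosity study."""
    return wf.initialize_design(
        wf.fixture_cube_corners(50),
        box=wf.BoundingBox(50, 50, 50),
        edge_type=wf.EDGE_TYPES["2HB"],
    )


@pytest.fixture
def loose_constraints():
    """Permissive constraint set: huge budget, tiny edge floor, no repulsion."""
    return wf.ConstraintSet(scaffold_budget=10**7, min_edge_nt=1)


def random_feasible_start(rng: np.random.Generator, n_points: int | None = None):
    """Random convex-position point cloud inside a 60 nm box, triangulated.

    Used as fuzzing material; retries until the hull uses every point.
    """
    n = n_points or int(rng.integers(5, 9))
    box = wf.BoundingBox(60, 60, 60)
    while True:
        pts = rng.uniform(10, 50, size=(n, 3))
        try:
            return wf.initialize_design(pts, box=box, edge_type=wf.EDGE_TYPES["2HB"])
        except wf.errors.TriangulationError:
            continue
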