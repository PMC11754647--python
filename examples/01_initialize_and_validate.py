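"""Initialize a design from preserved vertices and inspect it.

The framework never needs a full input mesh: the six face centres of a
50 nm cube are enough, and the initial surface is their triangulated
convex hull (an octahedron).
"""

import wireforge as wf

points = wf.fixture_parallelepiped_midfaces(50, 50, 50)
state = wf.initialize_design(
    points,
    box=wf.BoundingBox(50, 50, 50),
    edge_type=wf.EDGE_TYPES["2HB"],
)

report = wf.validate_mesh(state)
print(f"vertices={state.n_vertices} edges={state.n_edges} faces={state.n_faces}")
print(f"Euler characteristic V-E+F = {state.euler_characteristic()} (2 for a sphere)")
print(f"mesh valid: {report.valid}")
print(f"scaffold estimate: {wf.estimate_scaffold_nt(state)} nt "
      f"(M13mp18 offers {wf.M13MP18_NT} nt)")
print(f"min non-adjacent edge distance: "
      f"{wf.min_nonadjacent_edge_distance(state):.2f} nm")
# The octahedron uses ~1/3 of the scaffold; the annealer's job is to
# grow/reshape it toward a design goal without breaking feasibility.
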