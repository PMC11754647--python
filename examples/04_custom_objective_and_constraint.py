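"""Extend the framework: a custom objective and a custom constraint.

Any callable on a design state can serve as an objective (with a
direction) or as a boolean feasibility predicate. Here we maximise the
vertex count under a constraint that keeps every vertex out of the top
half of the box.
"""

import numpy as np

import wireforge as wf

def mean_vertex_height(state):
    return float(np.mean([p[2] for p in state.positions.values()]))

def all_vertices_in_lower_half(state):
    return all(p[2] <= 25.0 for p in state.positions.values())

objective = wf.ObjectiveSpec("vertex_count", "maximize", lambda s: s.n_vertices)

state = wf.initialize_design(
    [(10, 10, 2), (40, 10, 2), (25, 40, 2), (25, 20, 20)],
    box=wf.BoundingBox(50, 50, 50),
)
constraints = wf.ConstraintSet(
    scaffold_budget=wf.M13MP18_NT,
    min_edge_nt=10,
    custom=(("lower_half", all_vertices_in_lower_half),),
)
schedule = wf.AnnealingSchedule(total_iterations=1500, stall_stages=None)
problem = wf.AnnealProblem(state, wf.RuleSet(), constraints, objective, schedule)
result = wf.anneal(problem, np.random.default_rng(3))

best = result.best_state
_, pts = best.vertex_array()
print(f"started with {state.n_vertices} vertices, "
      f"best design has {best.n_vertices}")
print(f"max vertex z = {pts[:, 2].max():.2f} nm (constraint: <= 25 nm)")
print(f"mean vertex height = {mean_vertex_height(best):.2f} nm")
print(f"feasible: {wf.is_feasible(best, constraints).feasible}")
# The maximised objective is negated internally, so the optimiser's
# energy bookkeeping is identical to the minimisation case.
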