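"""Single-objective shape annealing: minimise porosity in a 50 nm cube.

A scaled-down version of the cube study (3,000 proposals instead of
20,000). Porosity = box volume / cylindrical DNA volume, so minimising
it packs as much DNA into the box as the 7249 nt scaffold budget and
the 2.5 nm inter-edge repulsion cutoff allow.
"""

import numpy as np

import wireforge as wf
from wireforge.studies import cube_porosity_problem

problem = cube_porosity_problem(proposals=3000)
print(f"start: porosity {problem.objective.energy(problem.initial_state):.3f}, "
      f"scaffold {wf.estimate_scaffold_nt(problem.initial_state)} nt")

result = wf.anneal(problem, np.random.default_rng(1))

best = result.best_state
print(f"auto-calibrated T0 = {result.t0:.3f}")
print(f"best porosity      = {result.best_energy:.3f}")
print(f"best design: {best.n_vertices} vertices, {best.n_edges} edges, "
      f"scaffold {wf.estimate_scaffold_nt(best)} / {wf.M13MP18_NT} nt")
# The scaffold estimate presses against the budget: the densest design
# is the one that spends (nearly) the whole scaffold.
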