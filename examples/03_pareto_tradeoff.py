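"""Multi-objective shape annealing: edge uniformity vs porosity.

Starting from the parallelepiped-midface octahedron with bounding-box
dimension moves (a, b, c, gamma) enabled, MOSA builds a Pareto archive
of feasible designs trading the variation index (0 = perfectly uniform
edges) against porosity (lower = denser).
"""

import numpy as np

import wireforge as wf
from wireforge.studies import tradeoff_problem

problem = tradeoff_problem(("variation_index", "porosity"), proposals=3000)
result = wf.run_mosa(problem, np.random.default_rng(2))

vecs = result.archive.vectors()
print(f"archive: {len(result.archive)} mutually non-dominated designs")
print(f"variation index range: {vecs[:, 0].min():.4f} .. {vecs[:, 0].max():.4f}")
print(f"porosity range:        {vecs[:, 1].min():.2f} .. {vecs[:, 1].max():.2f}")
most_uniform = result.archive.members[int(vecs[:, 0].argmin())]
densest = result.archive.members[int(vecs[:, 1].argmin())]
print(f"most uniform design: VI={most_uniform.vector[0]:.4f}, "
      f"porosity={most_uniform.vector[1]:.2f}")
print(f"densest design:      VI={densest.vector[0]:.4f}, "
      f"porosity={densest.vector[1]:.2f}")
# No archive member is best in both objectives: the archive exposes the
# trade-off so a designer can pick the compromise they can manufacture.
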