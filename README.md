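# wireforge

Generative design of **wireframe DNA origami** nanostructures by
graph-grammar shape annealing.

Wireframe origami folds a long single-stranded scaffold (typically
M13mp18, 7249 nt) along the edges of a polyhedral mesh, each edge a
bundle of 1, 2 or 6 DNA double helices. Designing such a mesh by hand
means juggling constraints that are easy to violate: the total scaffold
demand, minimum edge lengths that downstream sequence-design tools
accept, spatial envelopes, and separations between helix bundles.
`wireforge` inverts the workflow: instead of drawing a mesh, you state
*where material must exist* (preserved vertices/edges), *where it must
not* (excluded regions, a bounding box), and *what makes a design good*
(objective functions) — and a stochastic optimiser grows the mesh for
you.

## The model in brief

A design state `s` is a closed, edge-manifold triangle mesh in a
parallelepiped box (a, b, c, γ). Five grammar rules evolve it — vertex
extension quantised to the 0.34 nm/bp rise of B-form DNA, edge flips,
face division, vertex merging, and box resizing — and every candidate
must pass feasibility: scaffold estimate
`N_nt = Σ_edges passes · round(len/0.34)` within budget, per-edge
base-pair floors, containment, excluded regions, and a minimum distance
between non-adjacent edges. Search is simulated annealing with the
Metropolis rule

```
P_accept = exp(−(E_new − E_old)/T),   T ← αT  (geometric cooling)
```

for one objective, or multi-objective shape annealing (MOSA) with a
Pareto archive for two to three. Built-in objectives:

- **porosity** `V_box / V_DNA` (cylindrical bundle model) — utility;
- **variation index** — population σ of mean-normalised edge lengths —
  uniformity;
- **scaffold usage** `|N_nt − L| / L` — manufacturability with a fixed
  scaffold.

## Worked example

```python
import numpy as np
import wireforge as wf
from wireforge.studies import cube_porosity_problem

problem = cube_porosity_problem(proposals=3000)   # 50 nm cube, 2HB edges
result = wf.anneal(problem, np.random.default_rng(1))
```

Running `python examples/02_single_objective_porosity.py` prints:

```
start: porosity 9.712, scaffold 6024 nt
auto-calibrated T0 = 2.422
best porosity      = 8.070
best design: 10 vertices, 24 edges, scaffold 7248 / 7249 nt
```

The cube-corner start already uses 6024 nt of scaffold; annealing adds
and reshapes edges until the 7249 nt budget is nearly exhausted
(7248 nt), driving porosity — box volume per unit DNA volume — down
from 9.71 to 8.07. The multi-objective variant
(`examples/03_pareto_tradeoff.py`) instead returns an archive of
mutually non-dominated designs:

```
archive: 26 mutually non-dominated designs
variation index range: 0.0000 .. 0.3016
porosity range:        8.48 .. 23.45
```

— perfectly uniform designs (variation index 0) sit at one end of the
front, dense designs (porosity 8.5) at the other, and no member beats
another in both objectives.

The other examples show initialization/validation, custom objectives
and constraints, and mesh export (ASCII PLY/OBJ for sequence-design
pipelines, label-preserving JSON). A thin CLI wraps the same drivers:

```bash
wireforge generate --config problem.yaml --seed 7 --outdir run/
wireforge pareto   --config problem.yaml --outdir run/
wireforge report   run/
```

## Layout

```
src/wireforge/
  mesh.py          mesh model, hull initialization, nucleotide accounting
  grammar.py       the five rewrite rules + random rule application
  constraints.py   feasibility checks and the custom-constraint API
  objectives.py    built-in objectives and the custom registry
  anneal.py        single-objective shape annealing
  mosa.py          multi-objective annealing and the Pareto archive
  studies.py       the two reference study definitions
  config.py / meshio.py / fixtures.py / runs.py / cli.py
docs/methods.md    full model description, defaults and limitations
examples/          one short narrative script per capability
```
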