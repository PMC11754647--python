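# Methods

## The design model

A candidate wireframe DNA origami nanostructure is represented as a
closed, edge-manifold triangle mesh stored as a labelled undirected
graph: vertices carry Cartesian positions (nm) and a *preserved* flag,
edges map to mesh edges (also flaggable as preserved), and oriented
triangular faces close the surface. A parallelepiped bounding box
(a, b, c, γ) with volume `a·b·c·sin γ` confines the structure; optional
axis-aligned *excluded regions* must stay free of material. Edges will
be realised physically as DNA helix bundles (1, 2 or 6 double helices),
so edge lengths convert to nucleotide counts through the 0.34 nm/bp
axial rise of B-form DNA: per-helix base pairs are
`round(length / 0.34)` (round half-to-even) and the scaffold demand of
an edge multiplies by the number of scaffold passes through the bundle
(one per helix, the DAEDALUS-style routing convention; configurable).
The total scaffold estimate is the per-edge sum; no per-vertex overhead
is added by default because vertex staple accounting is tool-specific —
an additive per-vertex correction term is exposed and defaults to 0.

The design starts from the user's preserved geometry alone: the initial
surface is the triangulated convex hull of the preserved vertices, the
canonical minimal closed triangulation. Preserved vertices interior to
the hull, coplanar inputs, or preserved chords that are not hull edges
are rejected — a constrained (non-convex) initial triangulation is out
of scope. If the hull violates any constraint the run refuses to start.

## Grammar rules

Five local rewrite rules evolve the design while keeping every state a
valid triangulated closed surface:

| rule | effect | counts |
|---|---|---|
| `extend_vertex` | move a free vertex by k·0.34 nm along a random direction | V, E, F fixed |
| `edge_flip` | rotate the diagonal of two adjacent triangles | V, E, F fixed |
| `divide_face` | insert a vertex at a face centroid | V+1, E+3, F+2 |
| `merge_vertex` | remove a free vertex (degree-3 removal or edge collapse) | inverse of division |
| `resize_box` | change one of a, b, c, γ within bounds | geometry envelope |

The 0.34 nm quantisation is applied to the *extension displacement*
(so design changes happen in whole-nucleotide steps), not to every edge
length — forcing all edge lengths to exact multiples simultaneously is
geometrically overconstrained; lengths are quantised to nucleotides only
in the scaffold estimate. Extension directions are drawn uniformly on
the sphere and k uniformly in [k_min, k_max]. Rules are pure functions
returning new immutable states, so a rejected candidate never corrupts
the current solution. A random rule application draws rules by
(configurable, default-equal) weights and retries until a candidate
passes the full feasibility check, up to a retry budget; exhaustion is
reported to the optimiser as a null move.

Validity after every rule is re-checked: all faces triangular and
non-degenerate, every edge bordering exactly two faces, every vertex
link a single cycle, and no two faces over the same vertex set (which
excludes zero-volume "pillow" meshes that are topologically closed but
physically meaningless). Face–face self-intersection is not checked by
default (rules are local and the repulsion constraint keeps separated
edges apart); a strict O(F²) check can be added as a custom constraint.

## Constraints

Feasibility is the conjunction of:

- **topological** — scaffold estimate ≤ budget (M13mp18's 7249 nt by
  default) and every edge ≥ a per-helix base-pair floor (default 31 bp,
  a typical minimum for automated wireframe sequence-design tools;
  configurable per edge type because the exact floor is tool-specific);
- **spatial** — all vertices inside the (possibly sheared) bounding box
  and no edge segment passing through an excluded region, tested by
  exact slab clipping of the segment against the open box (grazing a
  face is not a violation);
- **repulsion** — minimum distance between non-adjacent edges ≥ a
  cutoff (vectorised clamped segment–segment distances over all
  non-adjacent pairs), a proxy for electrostatic repulsion between
  helix-bundle backbones;
- **custom** — user predicates on the full design state; a predicate
  that raises is logged and counted as a violation, never as a pass.

The scaffold constraint is implemented as an inequality (≤ budget):
designs are driven *toward* full scaffold use by the scaffold-usage
objective rather than by an equality constraint.

## Objectives

- **porosity** = V_box / V_DNA with V_DNA the sum of per-edge cylinders
  at the bundle diameter (defaults 2/4/6 nm for 1HB/2HB/6HB). Cylinder
  overlap at vertices is deliberately not de-duplicated — the quantity
  is an estimate and the simple sum keeps it strictly monotone in the
  edge set. Lower porosity = denser structure (a utility heuristic).
- **variation index** = population standard deviation of edge lengths
  divided by their mean (normalisation by the mean makes the measure
  scale-free; the population rather than sample deviation is used so a
  single-edge design scores exactly 0). 0 = perfectly uniform edges.
- **scaffold usage** = |N_nt − L| / L against a fixed scaffold length L
  (7249 nt default): a manufacturability measure minimised when the
  design consumes exactly one scaffold.

Custom objectives register by name with a direction; maximisation is
handled by negating the value internally so both optimisers always
minimise. Non-finite objective values raise immediately.

## Single-objective shape annealing

Proposals come from the random grammar applicator (feasible-only);
acceptance follows the Metropolis criterion: always accept
improvements, otherwise accept with probability `exp(−ΔE/T)` against a
uniform draw in (0, 1). Temperature cools geometrically (`α = 0.95`
default) after every stage of 50 proposals. The initial temperature is
auto-calibrated, unless given, so the mean worsening move of a short
(100-proposal) random walk from the start would be accepted with
probability 0.8 — a standard heuristic that makes the hot phase
genuinely explorative regardless of the objective's scale. Over the
final 30% of the run a ramp shrinks the maximum extension step linearly
to one base pair for fine-tuning. The best state ever seen is returned
(elitism) together with a per-proposal trace (energies, temperature,
acceptance, rule, scaffold estimate). Runs stop at the iteration budget
or, optionally, after three consecutive stages without an acceptance.
A run is a pure function of (configuration, seed).

## Multi-objective shape annealing (MOSA)

Two or three objectives are tracked as an energy vector (more only via
an explicit override — the approach is validated for 2–3). An archive
maintains all mutually non-dominated feasible designs; dominance is the
standard strict Pareto order under minimisation. Acceptance is
Suppapitnarm-style: a candidate not dominated by the current state and
not dominated by the archive is accepted outright; otherwise it is
accepted with probability `Π_i exp(−max(0, ΔE_i)/T_i)` under
per-objective temperatures calibrated independently (same 80% rule) and
cooled on a shared schedule. Every 5 stages (configurable) the walk
returns to a uniformly sampled archive member to spread coverage along
the front. The archive is uncapped by default; when capped, members are
pruned by crowding distance in objective space, never dropping
per-objective extremes. These acceptance/return-to-base conventions are
this package's own; they are standard MOSA practice, not an attribution.

## Reference studies and problem sizes

`studies.py` fixes the two benchmark problems:

- **cube porosity study** — porosity minimisation; 50 nm cube box, 2HB
  edges, cube-corner preserved vertices, 7249 nt budget, 2.5 nm
  repulsion cutoff, 20,000 proposals per seed, 5 seeds. With these
  settings the search saturates the scaffold budget (the best designs
  use 7248/7249 nt), giving a converged porosity of ≈ 8.1; the
  geometric floor at full scaffold use in this box is
  125000/(4π·1232.3) ≈ 8.07.
- **trade-off studies** — variation index (or scaffold usage) versus
  porosity from the parallelepiped-midface start, box moves on, 20,000
  proposals. The uniformity study retains perfectly uniform designs
  (variation index 0) in its archive and consistently produces larger
  archives than the manufacturability study on matched seeds, because
  scaffold usage admits far fewer near-optimal trade-offs.

The study sizes (20,000 proposals, 5 seeds) were chosen as the point
where the single-objective study's best value stops improving; larger
budgets change the converged porosity by < 0.01.

## What the synthetic inputs do and do not show

All inputs are generated geometry (cube corners, face midpoints, random
convex point clouds); there are no measured data. Passing tests
demonstrate the correctness of the mesh machinery, constraint logic and
optimisers, and the qualitative behaviours of the studies (budget
saturation, trade-off structure, archive-size disparity). They cannot
speak to folding thermodynamics, mechanical rigidity or experimental
yield of the generated designs — those require sequence design and
simulation/characterisation downstream of the exported meshes.

## Numerical choices and degenerate inputs

- round half-to-even for length→bp conversion (`numpy.rint`).
- zero-length edges raise; faces with squared-area below 1e-9 nm⁴ count
  as degenerate.
- box containment uses a 1e-9 relative tolerance in box-fractional
  coordinates; excluded-region tests shrink the region by 1e-9 nm so
  boundary contact does not count as intrusion.
- segment–segment distances use the clamped closest-point algorithm,
  vectorised over all non-adjacent pairs; `inf` when no such pair.
- ties in Metropolis (ΔE = 0) are accepted (exp(0) = 1).
- equal objective vectors: neither dominates; an exact duplicate of an
  archive member is not inserted.

## Known limitations

- The initial triangulation is the convex hull; preserved interior
  chords and non-convex starts are unsupported.
- Excluded regions are axis-aligned boxes only.
- No surface self-intersection check by default; strongly non-convex
  evolutions rely on the repulsion cutoff to stay physical.
- The scaffold estimate ignores vertex/staple overhead unless the
  per-vertex correction is set; absolute nucleotide counts are
  estimates to be refined by the downstream sequence-design tool.
- Genus changes are unreachable by the rule set (all states are
  genus-0, V − E + F = 2).
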