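# Methods

## The processes

Both walk types live on the unit hypercubic lattice Z^d (d ≥ 2), held as a
mutable graph with lazily materialized vertices: touching a vertex creates
its 2d axis neighbors and unit edges on demand, so walks are unbounded
without preallocating a window.  A vertex id is its original integer
coordinate tuple and doubles as its position; merges never move positions,
so the id/position distinction never reopens.  Edges are bi-directed with a
direction label per orientation; only the label of the stored orientation
is kept, the reverse being its entrywise negation (preserved exactly by the
label recalculation below).

**Growing SAW (kinetic growth walk).**  From the tip, one edge is chosen
uniformly at random among the tip's non-self-avoiding edges (equivalently,
edges to unvisited vertices) and traversed.  The walk stops in the first
configuration where no such edge exists.  This process is distributionally
distinct from uniform sampling of static self-avoiding walks; its 2D mean
trapping length in our runs (≈ 70.6 at n = 10,000) matches the classical
value ≈ 70.7 for this process, which we use as an external anchor of
correctness.

**Fiber walk.**  A growing SAW in which each elongation step triggers a
contraction around the new tip v.  With g the label of the traversed edge,
every outgoing tip edge is selected for contraction iff

1. its label has no entry opposite in sign to a nonzero entry of g, and is
   not equal to g (it is "incident from the side" of the growth direction);
2. it is not self-avoiding.

Each selected edge's far vertex w is merged into v in label-lexicographic
order: w's edges are re-attached to v with labels combined entrywise as
sign(a+b) (so entries stay in {−1,0,+1}: opposite directions cancel, zero
is the identity), lengths recomputed from endpoint positions, and
contraction counts incremented by one; the merge edge is discarded.  If v
already has an edge to an inherited target the two collapse onto one edge
keeping the larger contraction count and the self-avoiding flag if either
carried it (the lattice stays a simple graph).  Inherited edges ending at a
fiber vertex become self-avoiding.  Because every contracted edge joins a
fiber vertex to the rest of the lattice, any non-unit edge at a freshly
visited vertex leads to a fiber vertex, is self-avoiding on arrival, and is
therefore never selected — which bounds merges per step by 2(d−1).

The selection rule is the operational reading of "no movement opposite to
the current growth direction, different from the elongation step".  A
stricter variant (label differing from g in more than one entry) is easily
swapped in behind `select_lateral_edges`; it merges nothing after diagonal
steps and roughly doubles 2D stopping times, which is how we confirmed the
operational rule as the one consistent with the model's published stopping
behavior.

**Stopping.**  A walk is stopped iff every tip-incident edge is
self-avoiding.  Fiber edges are flagged both `in_fiber` and
`self_avoiding`, making the stopping test uniform; statistics that need
"self-avoiding but not fiber" filter on both flags.

## Randomness and reproducibility

Each walk owns a stdlib `random.Random` seeded explicitly; ensembles derive
per-walk seeds deterministically from (ensemble seed, walk index, attempt)
via `numpy.random.SeedSequence`.  Feasible edges are always enumerated in
(label, target) lexicographic order, so RNG consumption — hence every run —
is platform-independent and bit-reproducible.  Every mutation (vertex/edge
creation, flag changes, merges) is journaled; undoing a step replays the
journal inverse, restoring a byte-identical serialized state.

## Backtracking restarts

Scaling ensembles need walks of a fixed length (200 steps), which natural
stopping rarely reaches in 2D.  Trapped walks are resolved depth-first: the
last step (with its merges) is undone, the undone choice is excluded at
that depth, and a fresh uniform choice is drawn among the remaining
feasible edges; exclusion sets are cleared when a depth is re-entered along
a new prefix.  Escaping a sealed pocket can require exhausting an
exponentially large subtree, so the search carries a budget (default
15,000 undo events, chosen to keep a 1,000-walk 2D ensemble to minutes on
one CPU); a walk that exhausts it is re-run from scratch with a derived
fresh seed and counted in `ScalingEnsemble.n_reseeded` (typically 15–25% of
2D fiber walks, rare in 3D/4D, where trapping itself is rare).

This composition detail matters quantitatively: reseeded walks replace
configurations that sealed themselves in early, so the 2D fiber-walk MSD
exponent moves by a few hundredths as the budget varies (larger budgets
admit more compact configurations and lower the fitted exponent).  We state
it openly because the restart protocol is the one genuinely
underdetermined ingredient of the ensemble definition.  A `rejection`
policy (discard and resample whole walks) exists for sensitivity checks at
short lengths; it is hopeless at length 200 in 2D.

Stopping-time ensembles never restart; the two protocols are separate code
paths.  Walks reaching max_steps unstopped enter the stopping CDF censored
at max_steps and are reported separately (16 of 10,000 for the 2D growing
SAW at max 300; none for the fiber walk).

## Boundary reconstruction (2D)

The expansion boundary derives from the face dual of the lattice faces
adjacent to the fiber, refined by the intermediate lattice: on each
walk-incident non-fiber edge of length L and contraction count c, a vertex
at offset L/(2(c+1)) from the fiber endpoint.  The formula reduces to the
half-edge midpoint on unit edges, keeps the absolute offset at 0.5 on the
axis-aligned contracted classes (lengths 2 and 3), and leaves a central gap
≥ 1 across length-√5/3 self-avoiding edges — the gap too narrow for another
fiber to grow in between and expand, which is the purpose of the
compensation.

Assembly builds one star-shaped cell per fiber vertex through (i) the
intermediate point of every incident edge (half length for fiber edges) and
(ii) between angularly consecutive edges, the dual point of the enclosed
face, found by tracing the face with the planar rotation rule and taking
its centroid (on unit squares this is the classical face center; the traced
centroid matters on contracted triangular faces, where it is what keeps
right-angle turns singularity-free).  Where no small face closes the wedge
the parallelogram point of the two reaches stands in; where consecutive
edges are opposite or reflex (near stopped tips) the cell gets support
points at the smaller reach so it cannot pinch through its vertex.  Thin
strips along fiber edges (half-width 0.15, below the smallest possible
intermediate offset √2/4) keep consecutive cells connected.  The union of
all pieces dissolves shared cell walls — precisely the non-unique dual
edges that do not belong to the boundary — and its outer ring, oriented
counter-clockwise, is the boundary polyline.  Trapped pockets enclosed by
the walk are not carved out of the polyline; their count is reported as
`n_pockets`.  Simplicity is understood as "no two boundary segments cross
transversally": where a pocket grazes the outer loop the ring may touch
itself at isolated vertices, a measure-zero artifact of the construction.

The right-angle report checks, for every 90° turn of the fiber, that the
boundary contributes a vertex strictly inside the turn's 90° wedge (within
1.5 lattice units) and that the two segments meeting at the nearest such
vertex are not both axis-parallel and mutually perpendicular.  Turns whose
inner side lies deep inside the expanded region (no boundary within 0.9
units of the wedge) pass vacuously.  On uncontracted growing SAWs the
boundary does carry right angles — reproducing that contrast is the point
of the model.

Catmull–Clark smoothing is provided as its curve restriction (cubic
B-spline corner cutting: vertex point (p[i−1]+6p[i]+p[i+1])/8 plus edge
midpoints, doubling the vertex count per iteration).  It is cosmetic output
only and enters no statistic.

## Ensemble statistics

**Stopping times.**  Empirical CDF and median of the walk length at the
first stopping configuration (2D, max 300 steps).  The two walk types are
compared with the standard two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`); the package asserts the qualitative conclusion
(distinct distributions at α = 0.05) rather than any printed p-value.

**MSD scaling.**  Per step k, the mean over walks of the squared Euclidean
distance from the origin position to the k-th fiber vertex (positions are
unaffected by merges).  The scaling exponent is ν = slope/2 of the
least-squares line on log MSD vs log steps inside the scaling region,
anchored by the simple random walk ν = 1/2 (a vectorized ordinary-walk
control validates the pipeline).  The scaling region is the maximal suffix
[s, max], s ≥ 30, on which 5-point centered-difference local slopes deviate
from the terminal slope by less than 0.1.  Local slopes are evaluated on a
log-uniform resampling (33 grid points) of the curve so the window spans a
fixed step ratio (≈ 2×); on raw per-step points the late-curve spacing
(Δlog N ≈ 0.02) would amplify Monte-Carlo noise into slope fluctuations of
order 0.5 and no region would ever settle.  Clamped edge windows are
excluded from the settling test.  Errors are bootstrap standard errors from
resampling whole walks (not steps) with replacement, 1,000 replicates by
default.

**Contraction scaling.**  Same region rule and bootstrap applied to the
mean cumulative merge count per step of the final (post-backtracking) walk;
the exponent is the raw log-log slope, not halved.  Our faithful count
gives ≈ 0.99 in every dimension — merges per step start at 2(d−1) and decay
mildly as the environment crowds, so the cumulative count is slightly
sublinear.  A counter that survived undo (counting merges of abandoned
excursions) would push the 2D exponent far above 1 while leaving 3D/4D
unchanged, since only 2D walks backtrack heavily.

**Edge-length classes.**  Exact tallies (lengths rounded to 6 decimals) of
fiber-edge and self-avoiding-edge lengths over an ensemble; in 2D these
realize exactly {1, √2, 2} and {1, √2, 2, √5, 3}.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| stopping ensembles | n = 20,000, max 300 steps, 2D | acceptance script; tests use n = 10,000 |
| scaling ensembles | 1,000 walks × 200 steps | tests use 300 walks and widen tolerances to 2× the bootstrap SE |
| backtrack budget | 15,000 undo events/walk | see above; configurable via `WalkConfig.max_backtracks` |
| region detection | threshold 0.1, start 30, window 5, 33 log grid points | all configurable |
| bootstrap | 1,000 replicates (tests: 300–400) | resamples walks |
| boundary strip half-width | 0.15 | strictly below min offset √2/4 |

## Known limitations

- The boundary is 2D only; 3D/4D walks simulate fully but expose no
  surface reconstruction.
- One fiber per lattice; no branching, no interacting fibers, no biased
  step probabilities.
- The backtracking budget biases scaling ensembles toward configurations
  that extend without deep search; exponents in 2D carry a protocol
  dependence of a few hundredths beyond their bootstrap errors.
- Enclosed-pocket topology is reported, not resolved: the outer ring keeps
  pockets inside.
- Exact stopping-time enumeration beyond short walks, and finite-size
  extrapolation of ν, are out of scope.
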