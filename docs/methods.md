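# Methods

This note records the models implemented in `beamsel`, the parameter
choices that matter, and what the synthetic setting does and does not
establish.

## Phantom and geometry

The phantom is a regular voxel lattice (right-handed patient-centred
frame, mm; +x left, +y anterior, +z superior; 0-based indices; voxel
position = centre). Structures are analytic solids (sphere, cylinder,
box) voxelised by centre-inclusion — a voxel belongs to a solid iff its
centre is inside — which makes membership unambiguous and testable.
Overlap is resolved by unique integer priorities: the lowest priority
number wins, the planning target volume (PTV) always first, so each
voxel carries exactly one label. Voxels outside the body are air and
excluded from every objective.

Annular structures are shells around a reference solid, computed from
the Euclidean distance transform of the reference mask (distance in mm,
anisotropic spacing respected): a shell holds the voxels at distance in
`(offset, offset + width]`. The default phantom surrounds the PTV with
three concentric 10 mm shells (A1–A3) whose falling maximum-dose bounds
grade the dose fall-off — these shells are what lets a plan with few
beams distribute surface dose evenly.

Default phantom (5 mm isotropic voxels): cylindrical body (radius
120 mm, height 200 mm), spherical PTV (radius 25 mm) at (50, 0, 0),
a cylindrical organ at risk (radius 15 mm, height 80 mm) abutting the
PTV laterally, and A1–A3. Objectives (prescription 20 Gy): PTV a = 100,
bounds [20, 22] Gy; OAR a = 5, max 12 Gy; A1/A2/A3 a = 1, max 20/15/10
Gy; body a = 1, max 8 Gy. The target importance is two orders above the
normal-tissue weights, standard practice so coverage dominates; the
shell bounds step down by roughly a quarter of the prescription per
centimetre. These bounds are attainable by construction with ~10 or
more well-spread beams.

Candidate nodes sit on the sphere of radius SAD = 800 mm around the PTV
centroid, placed by a deterministic Fibonacci spiral over a polar cap
(apex anterior, half-angle 110°) with a posterior exclusion cone
(half-angle 30°) standing in for the treatment couch. The seed only
rotates the spiral's starting azimuth; placement is otherwise
deterministic, and generation fails if the requested count violates the
configured minimum angular separation (default 5°). The cap and cone
parameters are configurable defaults, not measured values — the
manufacturer's collision-free node set is not public. Evenly-spread
subsets (e.g. 36 of 110) come from greedy farthest-point sampling
seeded with the globally farthest pair, so the two-node subset is
exactly the maximal-separation pair.

## Dose engine

The dose-influence matrix `d_ij` is computed per beam with an analytic
pencil kernel — this is a documented stand-in for a clinical dose
engine, chosen to be qualitatively water-like for a 6 MV beam, not a
validated dose model:

    d(r, depth, l) = C · (SAD/r)² · exp(−μ(depth − z_ref))
                       · exp(−l² / 2σ(depth)²),   σ(depth) = σ0 + k·depth

with defaults μ = 0.005 mm⁻¹, σ0 = 2 mm, k = 0.02, C = 0.01 Gy per
weight unit at z_ref = 15 mm depth on axis. Depth is the in-body path
length along the bixel ray, found by uniform ray marching at half the
minimum voxel spacing; `l` is the exact perpendicular distance from the
ray; `r` the source distance. Per bixel column, entries below 0.015% of
the column maximum are dropped (the threshold is applied per column;
the alternative global-maximum reading was rejected as less literal).
The model is exactly linear by construction — a limitation it shares
with any beamlet-superposition approach.

Fluence grids live in the beam's eye view at isocentre distance, with
bixels of 2 MLC leaf widths (7.7 mm, leaf-stacking direction) × 5 mm
(leaf travel). One grid row drives two adjacent leaf pairs moving
together, so a grid is capped at 13 rows × 23 columns (26 pairs,
115 × 100 mm maximum field). The grid is the bounding box of the
projected PTV voxel centres plus a 5 mm margin, snapped outward to
whole bixels; collimator rotation is fixed at 0° (the leaf-stacking
axis is chosen as superior as possible).

## Objective and optimiser

F is the sum over all voxels of objective-bearing structures of
`a·([d_min − d]₊² + [d − d_max]₊²)`; no normalisation by structure
volume (each voxel counts once). Targets carry both bounds; normal
tissues only a maximum. The gradient is
`∂F/∂w_j = Σ_i 2 a_i (−[d_min−d_i]₊ + [d_i−d_max]₊) d_ij`.

Minimisation uses projected L-BFGS (memory 10) with two numerical
choices that go beyond the bare update rule:

- **Two-metric projection.** The two-loop recursion acts on the free
  variables only (those with `w > 0` or negative gradient); bound-active
  coordinates take the raw gradient. Naively projecting the full
  quasi-Newton step can stall short of the optimum once bounds are
  active — on random small instances it remained > 1e-6 away from an
  independent solver's optimum in a noticeable fraction of cases,
  whereas the two-metric variant agrees to ~1e-10.
- **Backtracking Armijo line search** (start α = 1, halve, c = 1e-4) on
  the projected point, accepting only strict decreases, so the
  objective trace is provably non-increasing. Curvature pairs with
  `s·y ≤ 1e-12` are discarded. With empty memory the first step is
  projected steepest descent.

Iteration budgets follow the planning workflow: 40 for standalone
reference plans, 20 inside beam selection (fewer at reduced scale),
with early exit after three consecutive iterations of relative change
below 1e-10 — one slow iteration near an active-set change is not
convergence.

## Sequencing and direct aperture optimisation

The optimised fluence map of each beam is quantised to integer levels
(default: maximum apertures per beam + 2) by rounding `v·L/max(v)`.
Sweep (level) decomposition opens, per level `t`, the bixels with value
≥ t. A level whose open set is non-contiguous within a row cannot be a
single MLC shape, so it is split into one aperture per run rank (each
aperture takes one `[left, right)` interval per row); identical
consecutive shapes merge with summed weight. Uncapped, the weighted
mask sum reconstructs the quantised map integer-exactly — a tested
invariant. When the per-beam cap (default 5) is exceeded, the segments
with the largest weight × open area are kept and the plan is marked
approximate. No interdigitation or leaf-gap constraints are modelled.

DAO is weight-only: each aperture contributes one dose column (the sum
of its open bixels' d_ij columns) and the same projected L-BFGS
re-optimises the nonnegative weights starting from the sequencer's
values, so DAO can never worsen the objective. Aperture shapes are
fixed after sequencing; gradient-driven leaf motion is out of scope.
Apertures whose optimised weight falls below 1e-6 of the largest are
pruned, which is how plans end up using fewer nodes than they were
given.

## Evolutionary algorithm

Genome: ordered list of K beam indices; duplicates can arise from the
crossover accept-rule and are collapsed to the unique set for planning
(so a genome with duplicates effectively fields fewer beams — and pays
for it through the objective). Fitness is F after the inner pipeline;
evaluations are memoised on the unique beam set, which is exact because
the inner pipeline is deterministic.

Per generation: the fittest `⌈population/10⌉` individuals (minimum 2)
form the parent pool; each of `population` offspring draws two distinct
parents uniformly from the pool, builds each gene from parent A with
probability 0.4 (else B), redraws once if the gene already occurs in
the child and accepts a second duplicate, then mutates each gene with
probability 0.05 to a uniform random candidate. Offspring replace the
population wholesale; the best individual ever seen is tracked
separately (implicit elitism). At population 20 the pool degenerates to
the single top-2 pair; at population 100 the "randomly selected pair"
reading applies — the rule covers both. Offspring evaluation seeds
derive deterministically from (run seed, generation, index), so whole
runs are bit-reproducible. Importance factors are fixed within a run;
re-weighting means a new run with a new configuration.

A property of this scheme worth knowing: with a small population the
parent pool collapses diversity quickly, and on landscapes with a
single isolated optimum the mutation rate of 0.05 recovers a lost gene
only slowly. The enumerable test instance (3 of 8 beams) therefore uses
a fitness with a block of interchangeable zero-cost directions — the
realistic situation, since neighbouring orientations trade off almost
equally — on which recovery of the exhaustive optimum is reliable
across seed windows. Larger populations relax this, consistent with the
parameter-sweep harness showing population 100 finding slightly lower
optima at much higher cost.

## Metrics and the time model

DVHs are cumulative (fraction of structure voxels at or above each dose
bin edge; default bin 0.05 Gy). Conformity index = voxels at or above
the prescription anywhere in the body ÷ PTV voxels. Monitor units are
aperture weights times a configurable calibration (default 1 MU per
weight unit); MU per Gy divides by the prescription. Estimated
treatment time is additive:

    T = setup + n_nodes·(traversal + imaging) + n_apertures·reshape + MU/rate

with defaults 5 min setup, 10 s traversal and 5 s imaging per node, 3 s
reshape per aperture, 800 MU/min. These rates are calibrated only to
reproduce the characteristic *ordering* (more nodes → longer
treatment, with beam-on a secondary term); the absolute minutes of any
vendor's scheduling algorithm are not modelled.

## Problem sizes used in tests and the acceptance script

The clinical-scale study (110 nodes, 15 beams, population 20, 20
generations, 40+40 iterations) is supported by the API but the shipped
verification runs at reduced scale, which the convexity of the inner
problem and the scale-free EA rules make representative: the end-to-end
study uses the default 5 mm phantom with 40 candidate nodes, K = 10,
population 10, 10 generations and 5+5 inner iterations, compared
against 25 random subsets and full/even-subset reference plans;
statistical-stability runs use a 10 mm phantom, 20 candidates, K = 6,
population 10, 5 generations, 25 seeds. Optimiser and DAO correctness
are checked against independent bound-constrained solvers on random
instances of up to 30 voxels and 10 bixels.

## Limitations

- The pencil kernel has no heterogeneity, scatter kernels, or
  large-field corrections; absolute doses are internally consistent,
  not clinically meaningful. Passing tests establish the optimisation
  and selection machinery, not dosimetric accuracy on patients.
- The synthetic phantom has idealised convex anatomy; real plans face
  concave targets, PTV–OAR overlap trade-offs and CT heterogeneity.
- Monitor units are not part of the objective; the sweep sequencer
  produces many small segments, so MU per Gy is high for large node
  sets — a more conformal segmentation would reduce it.
- Node traversal ordering (path connection) and robot kinematics are
  out of scope; treatment time uses node count, not path length.
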