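# Methods

## The model: Euler characteristic summaries as contribution lists

Every engine in this package reduces a filtered cell complex to the same data
structure: a list of contributions `(f(σ), (−1)^dim(σ))`, one per cell σ, with
`f(σ)` the (scalar or vector) filtration value at which σ enters the sublevel
filtration `K_t = f⁻¹(−∞, t]`.  The Euler characteristic of any sublevel set
is then the sum of the deltas located at or below the query point.  For one
filtration parameter, sorting and prefix-summing the aggregated list gives
the full curve; for n parameters the aggregated multiset *is* the profile and
queries are linear scans.

Aggregation groups locations under **exact floating-point equality**.
Duplicate filtration values arise only from identical arithmetic (the same
pairwise distance, the same voxel minimum), so no tolerance is needed; a
tolerance would make the result depend on aggregation order.  The aggregated
list is sorted lexicographically, so serialized output is identical no matter
how the per-vertex or per-voxel work was scheduled.  The curve is
right-continuous (a cell with `f(σ) = t` belongs to `K_t`) and 0 before its
first jump (the empty complex).

## Vietoris–Rips engine

`V-R(X, r) = {σ ⊆ X : diam(σ) ≤ r}`, filtered by the diameter (longest
pairwise distance; 0 for vertices).  The user-facing `threshold` bounds the
**diameter**, not a ball radius: radius conventions differ by a factor of two
across the literature and exposing the diameter directly removes the
ambiguity (the CLI help repeats this).

Enumeration is exactly-once by construction: under a fixed vertex ordering,
each simplex is generated in the local graph of its minimal vertex, by
breadth-first extension of simplices with common *subsequent* neighbors
(neighbors strictly later in the ordering).  Extending a simplex by a vertex
v updates the filtration to `max(old, dist(v, current vertices))` and
intersects the extendable set with v's subsequent in-threshold neighbors.
Per-dimension (breadth-first) expansion keeps the memory per local tree
bounded by the widest level of the simplex tree.

Two ordering strategies are provided.  `given` keeps input order;
`ascending_degree` sorts by the number of in-threshold neighbors (ties by
original index), which evens out local-tree sizes — a hub processed early
owns nearly every simplex it touches, and a few huge trees dominate parallel
runtime.  The aggregated result is invariant to the strategy and to the
worker count; both invariances are tested.  Parallelism uses joblib over
per-vertex tasks, which are pure functions with no shared state.

The metric is pluggable (any symmetric non-negative callable); Euclidean via
`scipy.spatial.distance.cdist` is the default.  For multiparameter
filtrations, per-vertex values (e.g. `codensity`, the mean distance to the k
nearest neighbors, k = 10 by default as is common for spatial point patterns)
are extended to simplices by a user rule, default coordinate-wise max — the
only rule that is always monotone without further assumptions.  Monotonicity
is checked on every emitted simplex against its vertices and violations
raise.

## Cubical engine

Images of any dimension and channel count are filtered by the
**T-construction**: voxels are identified with top-dimensional cells and
every face enters at the minimum (coordinate-wise minimum per channel) of the
values of the top cells containing it.  The complex is the *closed* cube
complex of the voxel grid — an image of shape `(m_1, …, m_d)` has
`∏(2 m_i + 1)` cells — so a constant image is contractible (χ = 1) in every
dimension, and binary shapes get their textbook Euler characteristics (the
3×3 ring test yields χ = 0 before the center fills in).

Cells are emitted exactly once via a partition into per-voxel **upper
closures**: on the doubled coordinate grid, voxel x owns coordinates
`2x_i + 1` (its top cell extent) and `2x_i + 2` (the face toward the +1
neighbor; on the max-index boundary this face exists but has a single owner),
plus the min-index boundary coordinates 0 when `x_i = 0`.  Interior voxels
own 2^d cells; boundary voxels own up to 3 per boundary axis.  All owners of
the cells in voxel x's closure lie at index x or x+1 along each axis, so the
computation streams with a two-slice window along the last array axis
(`stream_contributions` accepts a lazy slab iterator).  A vectorized
whole-image path (`image_contributions`) expands the grid axis by axis with
`np.minimum`, exploiting that the min over a product of owner sets factorizes
per axis; the streaming and vectorized paths agree bit-for-bit and both equal
the brute-force materialized complex on random images.

Integer voxel values pass through exactly; floats are allowed.  The
propagation rule is injectable (a V-construction-style rule could be dropped
in), but only the coordinate-wise min uses the fast path.

## Multicritical cells

When a cell enters an n-parameter filtration at an antichain
`p_1, …, p_k` of pairwise incomparable points, its contribution must equal
`(−1)^dim` on the union of the cones above the `p_i` without double counting
on overlaps.  The support of the correcting contributions is contained in the
joins (coordinate-wise maxima) of subsets of entry points.  The
implementation seeds the target value at each entry point, then sweeps all
subset joins in a linear extension of the product order (total coordinate
sum, ties lexicographic) and inserts a correction wherever the accumulated
value deviates from the indicator target.  Correctness for *every* query
point follows because the down-set of any point is realized by a join of
candidates, where equality was enforced.  An independent inclusion–exclusion
closed form (`Σ_S (−1)^{|S|+1}` at `join(S)`) serves as the test oracle.
Comparable entry points are rejected rather than silently minimized, so
filtration bugs surface at the caller.

## Distances

Curves: merge both jump lists with signs flipped on the second and sum
`|EC(f_i)| · (f_{i+1} − f_i)`.  The absolute value matters: the signed sum
telescopes to a difference of areas, not the L1 norm.  Without an explicit
upper integration bound, the curves must share their terminal value
(otherwise the distance is infinite and a `ValueError` says so).

Profiles: the merged, sign-flipped contribution list spans an irregular grid
with at most N+1 breakpoints per axis; the EC difference is constant on each
cuboid and equal to its value at the lower corner.  The implementation
scatters deltas onto the grid and takes prefix sums along each axis, then
sums `|EC| ·` cuboid volume — `O(∏ N_i)` overall rather than the naive
`O(N^{n+1})`, which is what makes the 60-texture experiment (1770 pairwise
3-parameter distances) run in seconds.  Truncation is mandatory and has no
default: a silent default would make distances from different runs
incomparable.  Integration starts at the smallest merged breakpoint per axis
(below it the difference is identically zero) and contributions at or beyond
the truncation are dropped (their cones meet the box in measure zero).

## Vectorization

Curves are sampled at N evenly spaced points on `[0, f_max]` (inclusive;
resolution `Δ = f_max/(N−1)`; a jump exactly at a node is included by
right-continuity).  Sampling starts at 0 even if the first jump is negative —
negative filtrations should be shifted first.  The reconstruction error obeys
`‖ECC − vec‖₁ ≤ Δ(|K|/2 + F)` with F the total variation of the sample
vector; the test suite verifies the bound on random Vietoris–Rips curves and
also exhibits both failure modes of distance stability (a narrow spike on a
node: close curves, distant vectors; bumps strictly between nodes: distant
curves, equal vectors).  No analogous bound holds for profiles — cancelling
cell pairs between grid nodes can change the profile on an arbitrarily large
region — so none is asserted.  Profile sampling uses the same
scatter-and-prefix-sum trick as the distances, and is tested against
pointwise queries.

## Stability bench

Betti curves are sums of half-open indicators `[b, d)` over diagram points.
The 1-Wasserstein distance (sum of l∞ matching costs, unmatched points paying
their nearest-diagonal projection `(b+d)/2`) is computed exactly as a linear
assignment on the diagonal-augmented cost matrix
(`scipy.optimize.linear_sum_assignment`); the tests cross-check it against an
independent exhaustive enumeration over subset bijections.  The sweep draws
diagram pairs with births uniform in [0, 5] and persistences uniform in
(0, 5] — finite diagrams only, so every distance is finite — and checks
`‖β(C) − β(D)‖₁ ≤ 2 W₁(C, D)`; the constant 2 is attained by a single bar
against the empty diagram.  The curve-level corollary (ECC distance bounded
by the summed per-dimension bounds) is exercised by building Euler curves as
alternating sums of Betti curves of synthetic diagrams, since the package
deliberately computes no homology.

The profile perturbation check shifts every raw cell location by at most ϵ in
l∞ (clamped to `[0, f_∞]`) and verifies
`‖ECP(K) − ECP(K^ϵ)‖₁ ≤ |K| · n · ϵ^{n−1} · f_∞`.  The bound in this printed
form is specific to n = 2 (the per-cell difference region is a slab of
measure ϵ · f_∞^{n−1}, which equals ϵ^{n−1} · f_∞ exactly when n = 2), and
all checks run at n = 2.

## Synthetic data

The fixtures module is first-class, tested code; every experiment in the
repository runs on its output.

- `sample_sphere(n, dim, noise, seed)`: uniform points on the unit
  `dim`-sphere in ℝ^(dim+1) (Gaussian-normalize method) plus isotropic
  Gaussian noise.  `dim=1` gives noisy circles, `dim=4` the 4-sphere scale
  used for large benchmarks.
- `texture_image(spec)`: a 64×64 (default) RGB image with a stripes or checks
  pattern at 0/255 in one channel, i.i.d. Gaussian pixel noise (σ = 10 on the
  0–255 scale) in all channels, rounded and clamped to [0, 255].  Pattern
  period defaults to size/8.  These defaults are fixed choices representing
  mildly noisy 8-bit textures; the qualitative result below is robust to
  reasonable alternatives.
- `random_diagram(n, birth_range, persistence_range, seed)`: finite diagrams,
  deaths = birth + positive persistence.

All generators are pure functions of their seed.

What the texture population does and does not show: the 60-image batch (10
samples of each style × color class) reproduces the qualitative ordering of
mean profile distances — same style/same color < same style/different color <
different style/same color < different style/different color — demonstrating
that 3-parameter profiles separate both factors of a controlled two-factor
population.  It does not emulate the optics, staining variation, or spatial
correlation of real histology, so passing it says nothing about
classification accuracy on real slides.

## Problem sizes and numerical choices

Engine-versus-oracle equivalence uses pointclouds of up to 12 points
(brute-force subset enumeration is exponential) and images up to 6×6×3 voxels
with 1–3 channels; determinism checks use 25 points across workers ∈ {1, 2,
4}; the stability sweep uses 500 diagram pairs with up to 6 points each; the
perturbation and vectorization bounds use 100 random instances each; the
texture experiment uses the full 60-image batch at 64×64.  Bound checks allow
a 1e−9 absolute tolerance for float accumulation; engine/oracle comparisons
are exact (bit-for-bit) everywhere, which is possible because both sides
perform identical arithmetic per cell (a deliberate design constraint).

Known limitations: no sparsification or approximation of Vietoris–Rips
complexes (the worst case is genuinely 2^n − 1 simplices, and the engine will
faithfully enumerate them); profile distances cost the full irregular grid,
exponential in the number of filtration parameters; the Wasserstein solver
targets the small diagrams of the bench, not production optimal transport; no
persistence-diagram or homology computation.
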