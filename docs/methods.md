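# Methods

## The distance and its decomposition

For two rooted binary trees T1, T2 on the same n leaves, every 3-subset of
leaves induces one resolved topology per tree (binary trees cannot leave a
triplet unresolved), and

```
d(T1, T2) = C(n,3) − Shared(T1, T2),
```

where Shared counts the 3-subsets with equal induced topology.  Assigning
each triplet to the lowest common ancestor of its three leaves partitions
the triplets of a tree by node; therefore Shared can be accumulated as a
double sum over node pairs (v in T1, u in T2), which the algorithm
organizes as: an outer enumeration over v (leaf colorings of T1) and an
inner count over all u at once (the decomposition tree over T2).

**Coloring.** With the leaves of one child subtree of v colored red, the
other child's blue, and everything else uncolored, the triplets rooted at
v are exactly those with two leaves of one color and one of the other.
For an internal node u of T2 with child subtrees x and y holding x(r),
x(b), y(r), y(b) red/blue leaves, the triplets rooted at u compatible
with the coloring (same-colored pair joined under u) number

```
C(x(b),2)·y(r) + C(y(b),2)·x(r) + C(y(r),2)·x(b) + C(x(r),2)·y(b),
```

with C(k,2) := 0 for k < 2 — a convention used throughout the counter
algebra.  Summing over all u (one bottom-up pass) gives the per-coloring
compatible count; this is `oracle.count_compatible`, and running it for
every v explicitly is the O(n²) reference `oracle.quadratic_shared`.

## Smaller-half traversal (colorwalk)

The walk maintains two invariants: (1) before node v is processed its
entire subtree is red and the rest of the tree uncolored; (2) after the
recursion returns the whole tree is uncolored.  At v with smaller child
subtree S(v) and larger L(v) (ties broken to the first child): color S(v)
blue; harvest the sink's count; uncolor S(v); recurse on L(v); color S(v)
red; recurse on S(v).  A leaf visit uncolors the leaf, which realizes
invariant (2) uniformly at the recursion base.  Each leaf is recolored
exactly three times per ancestor whose smaller side contains it, plus one
final uncoloring, and a leaf has at most ⌊log₂ n⌋ such ancestors (the
containing subtree at least doubles at each), so the walk issues at most
n·(3⌊log₂ n⌋ + 1) color events after the orchestrator's initial all-red
pass.  The traversal uses an explicit stack of (node, stage) frames:
caterpillar trees drive the recursion depth to Θ(n), beyond Python's call
stack.  Harvesting happens at the end of the "color S(v) blue" step in
all cases, including single-leaf S(v).  Subtree recolorings are range
scans over a precomputed left-to-right leaf layout, in which every
subtree is a contiguous slice.

## Hierarchical decomposition tree (hdt)

Base components are one **L** per leaf and one **I** per inner node of
T2.  Edges of T2 are contracted greedily in passes; each contraction
joins the components above and below one edge into a **C** component by
one of two compositions:

* **case a** — the upper component is a C: the lower component extends
  its spine;
* **case b** — the upper component is an I and the lower one is
  *down-closed* (contains a complete subtree): the inner node caps it.

An edge defers when either endpoint was already consumed in the current
pass or neither composition applies (lower endpoint is an I, or an I sits
above a non-down-closed component).  After a pass, deferred edges forward
their endpoint references to the freshly created parents.  Down-closure
propagates from the lower child in case a and is false at creation in
case b (the inner node's other child edge still crosses the boundary);
the finished root component is marked down-closed, being the whole tree.
Edges are scanned in pre-order of T2 and deferred edges keep their
relative order, making builds byte-reproducible; the greedy argument is
order-agnostic.

At least a quarter of the live edges are contractible at the start of any
pass, and each contraction blocks at most two neighbors, so every pass
removes at least 1/12 of the live edges.  Consequently the number of
passes — and hence the HDT height — is at most
⌈log(2n−2)/log(12/11)⌉, and total construction work is O(n).  The
builder records per-pass edge/contractible/contracted counts so tests and
the acceptance script can assert these bounds directly (observed builds
are far below them).

**Counters.** Each component carries exact integers R, B (red/blue
leaves), rr̃, bb̃ (same-color pairs within one pendant subtree of the
spine), rb̂, br̂ (cross-subtree pairs ordered along the spine), and N
(compatible triplets wholly inside the component).  L components hold the
indicator counters of their leaf's color, I components all zeros.  For a
case-a merge of bottom (1) and top (2):

```
R = R₁+R₂          rr̃ = rr̃₁+rr̃₂          rb̂ = rb̂₂+rb̂₁+R₁·B₂
B = B₁+B₂          bb̃ = bb̃₁+bb̃₂          br̂ = br̂₂+br̂₁+B₁·R₂
N = N₁+N₂ + C(R₁,2)·B₂ + C(B₁,2)·R₂ + rr̃₂·B₁ + bb̃₂·R₁ + R₁·rb̂₂ + B₁·br̂₂
```

and for case b the bottom collapses into a single pendant subtree:
R = R₁, B = B₁, rr̃ = C(R₁,2), bb̃ = C(B₁,2), rb̂ = br̂ = 0, N = N₁.
Recoloring one leaf therefore updates only the leaf-to-root HDT path;
the path update recomputes the full merge at every ancestor even when
only one child changed — simpler, same asymptotics.  All arithmetic is
exact int64; magnitudes stay below 2⁶² for n up to ~2·10⁶
(C(n,3) ≈ n³/6), and the pure-Python paths use arbitrary-precision ints.

## Orchestration and engines

`triplet_distance(algorithm="hdt")` builds the HDT on T2, establishes the
walk's entry invariant with one O(n) bulk all-red pass (cheaper than n
individual O(log n) updates), and runs the walk with the HDT as the
counting sink; n < 3 short-circuits to distance 0, a convention we adopt
since there are no triplets to compare.  The convention of coloring T1
and decomposing T2 is arbitrary; `swap=True` exercises the mirror
configuration, and tests assert symmetry.

Two engines execute the identical arithmetic: a pure-Python walk feeding
`HDT.set_leaf_color` (the readable reference, used by most unit tests),
and a numba-JIT kernel (`_kernels`) that fuses the walk and the path
updates over flat int64 arrays.  The kernel is the default because the
inner loop runs ~100× faster, which is what lets the scaling check reach
n = 2¹⁶ in seconds; the test suite asserts the two engines return
bit-identical totals.

## Simulated data

The generators cover the shape spectrum relevant to the algorithm's
behavior: `yule` (split a uniform random leaf; balanced on average, depth
O(log n)), `uniform` (uniform random coalescent joins; less balanced),
`caterpillar` (maximally unbalanced; stresses recursion depth, the
recoloring budget and HDT balance), and `balanced` (best case).
`perturb_labels` applies k leaf-label pair swaps to a copy, spanning
distances from 0 to near-maximal without changing the shape.  Every
generator takes an explicit seed into its own `random.Random`, so any
configuration is bit-reproducible across platforms.  The simulator
produces uniformly random *shapes within each model only*: it does not
emulate branch lengths, extinction, or the correlated error structure of
trees estimated from real sequence data, so passing tests demonstrate
algorithmic correctness over topologies, not robustness of any biological
inference.

Defaults used by the validation suite: exactness is checked exhaustively
against brute force at n ≤ 25 (200 random pairs) and against the
quadratic reference at n ∈ {50, 200, 1000}; structural bounds at sizes up
to n = 10⁵; the runtime-scaling band (normalized time within 4× across
n = 2¹⁰ … 2¹⁶) mirrors how the algorithm's complexity was validated
empirically.  These sizes were chosen to exercise every asymptotic regime
of the data structures while keeping the default suite quick to run.

## Degenerate inputs and edge cases

* n = 1 and n = 2 are legal; the distance is 0 by definition.
* Multifurcations are rejected, not auto-resolved: the counting formulas
  assume binary nodes.  Duplicate and empty leaf labels are rejected.
* Trees must be rooted with a two-child root (or be a single leaf);
  unrooted re-interpretation is out of scope.
* Equal-size children of a node tie-break to the first child as the
  "smaller" subtree; the total is invariant to the choice.
* Which side is red vs blue is arbitrary (the compatible-count formula is
  color-symmetric); the quadratic reference fixes red = first child,
  the walk colors the smaller side blue — tests confirm both conventions
  agree.

## Known limitations

* Binary trees only; generalizing requires more colors and
  degree-dependent counter algebra.
* No branch-length-aware distance; topology only.
* The O(n log n) compressed-decomposition refinement and batched
  bottom-up recoloring are not implemented.
* The JIT kernel assumes counters fit in int64 (safe for n ≤ 2·10⁶).
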