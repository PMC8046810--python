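# Methods

## Model

A network snapshot is an undirected weighted graph G = (V, E, ω) stored as
a symmetric non-negative n×n matrix with zero diagonal; an edge exists iff
its weight is positive, so weight changes to/from zero are edge
deletions/insertions.  Inputs are correlation-derived, hence dimensionless
weights in [0, 1); negative correlations may be present on load and are
removed by thresholding.

The curvature lives on a 2-dimensional complex associated with the graph:
nodes are 0-faces, edges 1-faces, and 2-faces are short cycles.  Two
enumeration modes exist:

* **chordal** (production default): 2-faces are triangles and cycles of 4
  or 5 nodes *together with* a triangulation obtained by gluing graph
  triangles along shared edges — two triangles sharing one edge (order 4),
  or a path of three triangles glued along two distinct chords (order 5).
  A cycle admitting several triangulations contributes one face per
  triangulation: the face is the gluing, not just its boundary.  Weights:
  triangle = mean of its three edge weights; glued face = sum of its
  triangles' weights.  Enumeration is chord-anchored (triangles by sorted
  adjacency intersection, 4/5-faces by merging triangles along shared
  edges), never a generic cycle search, keeping the cost near the face
  count rather than O(n^d).
* **all_cycles**: every simple cycle of ≤ d nodes is one face, weight =
  mean boundary edge weight for non-triangles.  This realizes the general
  complex on triangle-free graphs too and is the correct setting for the
  hanging-edge equivalence check below; it deliberately uses a library
  cycle enumerator since it only ever runs on small graphs.

An edge is incident to a face iff it is a *boundary* edge; internal chords
contribute only through face weights.  Node weight = mean incident edge
weight (0 for isolated nodes — they carry no edges, so the value never
enters a curvature).

The maximum order is capped at d = 5.  Past 5 the face enumeration cost
grows combinatorially with no change to the method, and 5 already captures
triangle, square and pentagon context; d is validated and larger values are
rejected.

## Curvature formulas and their agreement

The simplified per-edge curvature (README formula) sums face terms, an
endpoint term and a parallel term restricted to disjoint boundary co-edges
within shared faces.  The full reference formula instead sums over all
edges parallel to e in the face partial order — sharing an endpoint
(common immediate predecessor) XOR a shared 2-face (common immediate
successor) — each contributing the absolute difference of its shared-face
and shared-endpoint sums.  If no adjacent edge is *hanging* (adjacent but
on no simple cycle of ≤ d edges through e), every adjacent edge shares
both a node and a face with e, the parallel set degenerates to the
disjoint face-mates, and the two formulas coincide exactly; the
`prop1_check` helper verifies this edge-by-edge and raises if the
implication ever fails.  The agreement is independent of the face weights,
which the test suite checks by rescaling all face weights and recomputing.

Hanging-edge detection reduces to a bounded simple-path search: e′ = {v, x}
hangs off e = {u, v} iff no simple path of ≤ d−2 edges joins x to u while
avoiding v.  The number of candidate interior-node sequences of such paths,
Λ = Σ_{j=1}^{d−3} C(n−3, j)·j!, grows so fast with n (38,809 at n = 200,
d = 5) that hanging edges are essentially absent from dense networks —
which is why the simplified formula is the production default.

Numerics: accumulation in deterministic sorted order, plain doubles;
results are bit-reproducible across runs.  A face of non-positive weight
aborts the computation (it signals corrupt input weights).  Curvature is
homogeneous of degree 1 under global weight rescaling; the tests recompute
rather than assume this.

## Ollivier comparator

κ(e) = 1 − W₁(m_u, m_v) with m_x uniform on x's neighbors (zero idleness)
and hop-count ground distance, giving the classical range [−2, 1].  W₁ is
solved as an exact transportation LP (HiGHS); exactness matters because the
object of interest is the *sign* of κ near zero.  The uniform/hop variant
is this package's documented choice among the several Ollivier variants in
circulation.  The sign-combination search scans curated fixtures (triangle:
both positive; double-star bridge: Forman positive, Ollivier negative) and
random weighted graphs with weights drawn U(0.1, 1) — wider than the
synthetic study band, since large weight ratios are what make
negative-Forman edges reachable at small n — and stops once all four sign
pairs are witnessed.

## Anomaly statistic

Δₑ = C₁(e) − C₂(e) (control minus disease) over the union of the two edge
sets, absent pairs contributing curvature 0.  Outliers: |Δₑ| above a
cutoff, default twice the population standard deviation of the Δ values
(the Δ set is the full population of pairs, not a sample).  For comparison
against the weight baseline Λₑ = ω₁(e) − ω₂(e) ∈ [−1, 1], Δ values are
mapped by η(Δ) = (2Δ − high − low)/(high − low) onto [−1, 1]; a constant Δ
map has no scale and maps to zero.  Δ statistics use the union of edge
sets; a pair absent from both networks is 0 under either convention.

## Null model

Degree-preserving Markov-chain double edge swaps: pick two edges with four
distinct endpoints, rewire {a,b},{c,d} → {a,d},{c,b}, reject proposals
creating self-loops or duplicate edges or creating/destroying the pinned
pair under test.  Weights travel with the surviving half-edge pairing, so
the degree sequence and the multiset of edge weights are preserved exactly;
node strength (weighted degree) is *not* preserved — a documented
limitation of weighted swaps.  The swap count η (default 5·|E|) counts
*accepted* swaps, with a proposal cap of 100·η so rigid graphs (e.g. a
triangle) terminate and return unchanged.  Each of R replicate pairs
(default 100) randomizes both networks independently with per-replicate
seed streams spawned from one root seed, re-evaluates the curvature
difference at the pinned edge, and the observed Δ is summarized as a
population-std z-score (undefined when the null sample is degenerate);
|z| ≥ 2 is the significance label.  Per-edge re-evaluation uses a radius-2
ball around the edge's endpoints — every face incident to an edge lies
within two hops of its endpoints — making replicate ensembles cheap.

Null calibration: with the disease network replaced by an independent
randomization of the control, 5% of tested edges reached |z| ≥ 2 at R = 30
over 200 edge tests (the test suite pins this between 1% and 10%).

## Synthetic data

`random_weighted_network` draws G(n, p) topology with i.i.d. uniform
weights in [0.4, 1.0) — the post-threshold regime of sparsified correlation
networks, where the default τ = 0.4 sparsification is a no-op on synthetic
data by construction.

`planted_pair` emulates a localized disease alteration.  The disease copy
multiplies the target edge's weight by `effect` (clamped to the band) and
closes `k_close` new triangles through the target.  The design goal is a
perturbation that is local *in the 2-complex*: each closure node is chosen
to have no adjacency into the radius-1 neighborhood of the target's
endpoints and none to other closure nodes, and a randomly chosen target is
drawn from the least-triangulated edges with the largest supply of such
clean closure nodes.  Under these constraints the new faces incident to
the target are exactly the planted triangles, so the target's curvature
shifts by their face terms while every other edge sees at most one new
face — without them, glued 4/5-faces spawned by the closures leak
comparable curvature changes onto surrounding edges and the planted signal
is no longer identifiable as the top |Δ| edge.  Spoke weights are drawn at
the bottom of the weight band: light triangles weigh little, so the
target's face term ω(e)²/ω(f) responds strongly while the new edges' own
curvature stays small.  This is also the regime the weight baseline is
blind to: the target's weight moves by at most a factor `effect` while its
curvature changes by the full face terms.

What the generator does *not* emulate: subject-level sampling noise,
correlation structure between nearby edges (weights are i.i.d.),
hub/module organization of real connectomes, or negative correlations.
Passing the planted-recovery tests therefore shows the statistic separates
a face-level perturbation from an i.i.d. background — not that it ranks
anomalies correctly under realistic cohort variability.

## Problem sizes and defaults

| parameter | default | meaning |
| --- | --- | --- |
| τ (threshold) | 0.4 | entries < τ zeroed before analysis |
| d (order) | 5 | max nodes in a 2-face; d ∈ {3,4,5} |
| mode | chordal | face enumeration mode |
| cutoff | 2·std(Δ) | outlier threshold on |Δ| |
| R | 100 | null replicate pairs per edge |
| swap factor | 5 | accepted swaps = 5·|E| per randomization |
| weight band | [0.4, 1.0) | synthetic edge weights |
| effect / k_close | 1.5 / 3 | planted perturbation strength |

The test suite runs its stochastic checks at reduced sizes chosen to keep
the full suite under a couple of minutes on one CPU: oracle equivalence on
all connected graphs of ≤ 6 nodes plus 50 random graphs of ≤ 12 nodes;
formula-agreement suite on Q3/Q4/K2,2/K3,3/K2,2,2 with 10 random
weightings; null calibration at n = 24, R = 30, 200 edge tests; planted
recovery at n = 30, p = 0.2 over 20 seeds; sign search over at most 10,000
graphs of ≤ 8 nodes (stops early once all four combinations are found).

## Known limitations

* Chordal mode counts one face per triangulation; boundary-level
  deduplication is a documented alternative (the gluing is taken as the
  face object, matching the merge construction).
* The Ollivier variant (zero idleness, hop metric, uniform masses) is one
  of several in the literature; numerical κ values are variant-dependent
  even though the [−2, 1] range and the sign phenomenon are not.
* Weighted edge swaps preserve the weight multiset but not node strength.
* No multiple-testing correction across edges: the |z| ≥ 2 label is
  per-edge, and the outlier cutoff is a screening device, not an error
  rate.
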