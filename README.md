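# netcurv

Curvature-based anomaly detection for weighted networks, built around an
order-*d* 2-complex Forman–Ricci curvature.

## The problem

Given two snapshots of a network on the same node set — e.g. mean functional
connectivity matrices of a healthy cohort (*G₁*) and a patient cohort
(*G₂*), with brain regions as nodes and correlations as edge weights — which
connections changed in a structurally meaningful way?  Comparing raw edge
weights misses changes in an edge's *context*: the triangles and short glued
cycles it participates in.  Per-edge curvature summarizes exactly that
context, so the difference of curvatures between snapshots is a sensitive
anomaly statistic.

## The statistic

For an edge e = {u, v} with weight ω(e) > 0 the simplified order-*d*
curvature is

```
C(e) = ω(e) · [ Σ_{f ∋ e} ω(e)/ω(f)  +  (ω(u)+ω(v))/ω(e)
                − Σ_{(e′,f) : e,e′ ∈ f, e∩e′=∅} √(ω(e)ω(e′))/ω(f) ]
```

where *f* runs over 2-faces of the complex whose boundary contains e
(triangles, and cycles of up to *d* nodes built by gluing triangles along
shared edges), ω(v) is the mean weight of v's incident edges, ω of a
triangle is the mean of its three edge weights, and ω of a glued face is the
sum of its triangles' weights.  Zero-weight pairs have curvature 0.  A full
(reference) variant sums over all parallel edges — shared endpoint XOR
shared face — and coincides with the simplified formula whenever no adjacent
edge is "hanging" (i.e. every adjacent edge lies on some cycle of ≤ *d*
edges through e).

The anomaly pipeline computes Δₑ = C₁(e) − C₂(e) for every pair, flags
edges with |Δₑ| above twice the population standard deviation, compares the
[−1,1]-normalized Δ against the plain weight difference Λₑ = ω₁(e) − ω₂(e),
and attaches a z-score from a degree-preserving edge-swap null model that
pins the edge under test (default 5·|E| accepted swaps, 100 replicate pairs,
|z| ≥ 2 significant).  An exact Ollivier–Ricci comparator (uniform neighbor
distributions, hop metric, LP-solved Wasserstein-1) is included for sign
comparisons between the two curvature notions.

## Worked example

Simulate a control/disease pair with a planted, face-level perturbation at
one edge, then run the full analysis:

```sh
netcurv simulate --n 30 --p 0.2 --seed 0 --outdir sim
# wrote sim/control.txt, sim/disease.txt, sim/labels.txt
# perturbed edge: n025,n029

netcurv anomaly --control sim/control.txt --disease sim/disease.txt \
                --labels sim/labels.txt --replicates 100 --top-k 3 \
                --seed 1 --outdir out
# delta mean -0.122, std 0.495; 7 outliers (cutoff 0.989) -> out/
```

`out/outliers.tsv` ranks edges by |Δ|; the planted edge comes first:

```
edge_u  edge_v  curv_control  curv_disease  delta      norm_delta  z
n025    n029    1.254332      4.382620      -3.128289  -1.000000   -3.39395
n023    n025    0.000000      1.641324      -1.641324  -0.071505   -0.972522
n020    n025    0.000000      1.577511      -1.577511  -0.031658   -0.812722
```

The perturbation multiplied one edge weight by 1.5 and closed three
triangles through it: the edge's curvature jumps from 1.25 to 4.38
(Δ = −3.13, more than six standard deviations of the Δ distribution, null
z = −3.4, significant at the |z| ≥ 2 cutoff), while its raw weight changed
by only −0.26 (`out/comparison.tsv`) — the kind of contextual change a
weight-difference screen underrates.

The same analysis runs on real connectivity matrices: plain-text square
matrices plus a label file, thresholded at 0.4 by default
(`--threshold`), curvature order `--order 5`.

Library use mirrors the CLI:

```python
from netcurv import SynthSpec, Perturbation, planted_pair, curvature_map, delta_map

control, disease, target = planted_pair(
    SynthSpec(n=30, p=0.2, seed=0, perturbation=Perturbation(effect=1.5, k_close=3))
)
deltas = delta_map(curvature_map(control), curvature_map(disease))
assert max(deltas, key=lambda e: abs(deltas[e])) == target
```

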