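"""Order-d 2-complex Forman-Ricci curvature of weighted network edges.

For an edge e = {u, v} with weight w(e) > 0 the simplified curvature used
throughout the pipeline is

    C(e) = w(e) * [ sum_{f : e ~ f} w(e)/w(f)
                    + (w(u) + w(v)) / w(e)
                    - sum_{(e', f) : e, e' ~ f, e' disjoint from e}
                          sqrt(w(e) w(e')) / w(f) ]

where f runs over the 2-faces whose boundary contains e, node weights are
mean incident edge weights, and the last sum runs over boundary edges of
those faces sharing no endpoint with e.  The full (reference) formula
replaces the last sum with a sum over *all* edges parallel to e in the face
partial order, each contributing the absolute difference between its shared
face terms and its shared-endpoint terms; the two formulas coincide whenever
e has no hanging edges (no adjacent edge missing from every short cycle
through e).

Pairs with zero weight have zero curvature by definition.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .complexes import FaceSet, enumerate_faces, hanging_edges, node_weight, parallel_pairs
from .netio import WeightedNetwork

PROP1_TOL = 1e-9


def _fingerprint(net: WeightedNetwork) -> str:
    h = hashlib.sha256()
    h.update("\x1f".join(net.labels).encode())
    h.update(np.ascontiguousarray(net.weights).tobytes())
    return h.hexdigest()[:16]


@dataclass
class CurvatureTable:
    """Edge -> curvature map for one network at one (order, mode).

    Lookup is symmetric in the two node labels, and any pair absent from the
    map (zero-weight pair) has curvature 0.
    """

    d: int
    mode: str
    values: dict[tuple[str, str], float]
    fingerprint: str = ""
    labels: tuple[str, ...] = field(default_factory=tuple)

    def value(self, u: str, v: str) -> float:
        key = (u, v) if u <= v else (v, u)
        return self.values.get(key, 0.0)

    def edges(self):
        return self.values.keys()

    def __len__(self) -> int:
        return len(self.values)


def _node_weights(net: WeightedNetwork) -> np.ndarray:
    return np.array([node_weight(net, i) for i in range(net.n_nodes)])


def _eq2_terms(net, i, j, faces: FaceSet, nw: np.ndarray) -> float:
    """Bracketed sum of the simplified formula for existing edge (i, j)."""
    w = net.weights
    we = w[i, j]
    face_term = 0.0
    parallel_term = 0.0
    for f in faces.faces_with_edge(i, j):
        if f.weight <= 0:
            raise ValueError(f"face {f.boundary} has non-positive weight {f.weight}")
        face_term += we / f.weight
        for a, b in f.boundary_edges():
            if a not in (i, j) and b not in (i, j):
                parallel_term += np.sqrt(we * w[a, b]) / f.weight
    node_term = (nw[i] + nw[j]) / we
    return face_term + node_term - parallel_term


def forman_curvature(
    net: WeightedNetwork,
    e: tuple[str, str],
    d: int = 5,
    faces: FaceSet | None = None,
    mode: str = "chordal",
) -> float:
    """Simplified order-d curvature of one edge (the pipeline default).

    ``faces`` may be precomputed with :func:`netcurv.complexes.enumerate_faces`
    and shared across edges; otherwise it is enumerated here.
    """
    i, j = (net.index(x) for x in e)
    we = net.weights[i, j]
    if we == 0:
        return 0.0
    if faces is None:
        faces = enumerate_faces(net, d, mode)
    nw = _node_weights(net)
    return float(we * _eq2_terms(net, i, j, faces, nw))


def forman_curvature_full(
    net: WeightedNetwork,
    e: tuple[str, str],
    d: int = 5,
    faces: FaceSet | None = None,
    mode: str = "chordal",
) -> float:
    """Full order-d curvature of one edge (reference formula).

    The parallel sum runs over every edge e' parallel to e (shared endpoint
    XOR shared face), each contributing
    ``| sum_f sqrt(w(e) w(e'))/w(f) - sum_v w(v)/sqrt(w(e) w(e')) |`` with f
    over faces containing both edges and v over shared endpoints.  Global,
    hence intended for small graphs.
    """
    i, j = (net.index(x) for x in e)
    w = net.weights
    we = w[i, j]
    if we == 0:
        return 0.0
    if faces is None:
        faces = enumerate_faces(net, d, mode)
    nw = _node_weights(net)

    face_term = 0.0
    for f in faces.faces_with_edge(i, j):
        if f.weight <= 0:
            raise ValueError(f"face {f.boundary} has non-positive weight {f.weight}")
        face_term += we / f.weight
    node_term = (nw[i] + nw[j]) / we

    parallel_term = 0.0
    for (pu, pv), _ in parallel_pairs(net, e, faces, formula="eq1"):
        a, b = net.index(pu), net.index(pv)
        wep = w[a, b]
        shared_face = 0.0
        for f in faces.faces_with_edge(i, j):
            if (min(a, b), max(a, b)) in f.boundary_edges():
                shared_face += np.sqrt(we * wep) / f.weight
        shared_node = 0.0
        for vtx in set((i, j)) & {a, b}:
            shared_node += nw[vtx] / np.sqrt(we * wep)
        parallel_term += abs(shared_face - shared_node)
    return float(we * (face_term + node_term - parallel_term))


def curvature_map(net: WeightedNetwork, d: int = 5, mode: str = "chordal") -> CurvatureTable:
    """Simplified curvature of every existing edge, from one shared face enumeration."""
    faces = enumerate_faces(net, d, mode)
    nw = _node_weights(net)
    values: dict[tuple[str, str], float] = {}
    iu, iv = np.nonzero(np.triu(net.weights, 1) > 0)
    for i, j in zip(iu.tolist(), iv.tolist()):
        we = net.weights[i, j]
        values[(net.labels[i], net.labels[j])] = float(we * _eq2_terms(net, i, j, faces, nw))
    return CurvatureTable(d, mode, values, _fingerprint(net), net.labels)


def edge_curvature_local(
    net: WeightedNetwork, e: tuple[str, str], d: int = 5, mode: str = "chordal"
) -> float:
    """Simplified curvature of one edge via a radius-2 neighborhood subgraph.

    Every 2-face incident to e lies within graph distance 2 of e's endpoints,
    so faces are enumerated on that ball only; node weights still come from
    the full network.  Used by the null-model machinery, which re-evaluates a
    single pinned edge on thousands of randomized networks.
    """
    i, j = (net.index(x) for x in e)
    we = net.weights[i, j]
    if we == 0:
        return 0.0
    w = net.weights
    ball = {i, j}
    frontier = {i, j}
    for _ in range(2):
        nxt = set()
        for x in frontier:
            nxt.update(int(y) for y in net.neighbors(x))
        nxt -= ball
        ball |= nxt
        frontier = nxt
    idx = sorted(ball)
    sub = WeightedNetwork(tuple(net.labels[k] for k in idx), w[np.ix_(idx, idx)])
    faces = enumerate_faces(sub, d, mode)
    si, sj = idx.index(i), idx.index(j)
    nw_full = np.zeros(sub.n_nodes)
    nw_full[si] = node_weight(net, i)
    nw_full[sj] = node_weight(net, j)
    return float(we * _eq2_terms(sub, si, sj, faces, nw_full))


@dataclass(frozen=True)
class Prop1Result:
    edge: tuple[str, str]
    has_hanging: bool
    eq1: float
    eq2: float

    @property
    def equal(self) -> bool:
        return abs(self.eq1 - self.eq2) <= PROP1_TOL


def prop1_check(net: WeightedNetwork, e: tuple[str, str], d: int = 5) -> Prop1Result:
    """Compare the full and simplified formulas on one edge (``all_cycles`` mode).

    An edge with no hanging edges must have identical values under both
    formulas; a violation indicates an implementation fault and raises.
    """
    faces = enumerate_faces(net, d, mode="all_cycles")
    hang = hanging_edges(net, e, d)
    eq1 = forman_curvature_full(net, e, d, faces=faces)
    eq2 = forman_curvature(net, e, d, faces=faces)
    res = Prop1Result(tuple(e), bool(hang), eq1, eq2)
    if not res.has_hanging and not res.equal:
        raise RuntimeError(
            f"edge {e} has no hanging edges but formulas differ: {eq1} vs {eq2}"
        )
    return res
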