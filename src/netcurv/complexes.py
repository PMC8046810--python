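"""The order-d 2-complex built on top of a weighted graph.

The curvature in :mod:`netcurv.forman` is defined on a 2-dimensional complex
associated with the graph: nodes are 0-faces, edges are 1-faces, and 2-faces
are simple cycles of at most ``d`` nodes (``3 <= d <= 5``).  Two enumeration
modes are supported:

``chordal`` (default, the empirical pipeline's mode)
    A 2-face is a triangle, or a cycle of 4 or 5 nodes *together with* a
    triangulation obtained by gluing triangles of the graph along shared
    edges.  A 4-face is two triangles sharing one edge; a 5-face is a path of
    three triangles glued along two distinct chords.  A cycle admitting
    several triangulations yields one face per triangulation.  Face weights:
    a triangle weighs the mean of its three edge weights; a glued face weighs
    the sum of its constituent triangle weights.

``all_cycles`` (exact, small graphs)
    Every simple cycle of at most ``d`` nodes is a face, once, whether or not
    it can be triangulated; non-triangle faces weigh the mean of their
    boundary edge weights.  This mode realises the general definition of the
    complex and is the right setting for checking the hanging-edge criterion
    under which the full and simplified curvature formulas agree.

In both modes an edge is incident to a face iff it is a *boundary* edge of
the face; internal chords of a triangulation contribute only through the
face weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .netio import WeightedNetwork

VALID_ORDERS = (3, 4, 5)


@dataclass(frozen=True)
class Face2:
    """A 2-face of the order-d complex.

    ``boundary`` is the face's boundary cycle in canonical orientation
    (node indices of the host network); ``triangulation`` is the tuple of
    sorted node triples gluing the face, empty for non-chordal faces found in
    ``all_cycles`` mode; ``weight`` is the face weight described above.
    """

    boundary: tuple[int, ...]
    triangulation: tuple[tuple[int, int, int], ...]
    weight: float

    @property
    def order(self) -> int:
        return len(self.boundary)

    def boundary_edges(self) -> tuple[tuple[int, int], ...]:
        b = self.boundary
        k = len(b)
        return tuple(tuple(sorted((b[i], b[(i + 1) % k]))) for i in range(k))


def _canonical_cycle(cycle) -> tuple[int, ...]:
    """Rotate/reflect a cycle so it starts at its minimum node, smaller neighbor second."""
    cycle = list(cycle)
    k = len(cycle)
    i = cycle.index(min(cycle))
    fwd = [cycle[(i + j) % k] for j in range(k)]
    bwd = [cycle[(i - j) % k] for j in range(k)]
    return tuple(fwd) if fwd[1] <= bwd[1] else tuple(bwd)


class FaceSet:
    """All 2-faces of one network at one (order, mode), with edge incidence."""

    def __init__(self, net: WeightedNetwork, d: int, mode: str, faces: list[Face2]):
        self.net = net
        self.d = d
        self.mode = mode
        self.faces = faces
        self._incidence: dict[tuple[int, int], list[int]] = {}
        for idx, f in enumerate(faces):
            for e in f.boundary_edges():
                self._incidence.setdefault(e, []).append(idx)

    def __len__(self) -> int:
        return len(self.faces)

    def faces_with_edge(self, i: int, j: int) -> list[Face2]:
        key = (i, j) if i < j else (j, i)
        return [self.faces[k] for k in self._incidence.get(key, ())]


def node_weight(net: WeightedNetwork, v: str | int) -> float:
    """Weight of a node: the mean weight of its incident edges (0 if isolated)."""
    i = net.index(v) if isinstance(v, str) else v
    if not 0 <= i < net.n_nodes:
        raise KeyError(f"unknown node index {i}")
    nbrs = net.neighbors(i)
    if len(nbrs) == 0:
        return 0.0
    return float(np.mean(net.weights[i, nbrs]))


def _triangles(net: WeightedNetwork) -> list[tuple[int, int, int]]:
    """All triangles (i < j < k), by sorted-adjacency intersection."""
    tris = []
    w = net.weights
    for i in range(net.n_nodes):
        ni = net.neighbors(i)
        ni = ni[ni > i]
        for j in ni:
            common = np.intersect1d(ni, net.neighbors(j), assume_unique=False)
            for k in common[common > j]:
                tris.append((i, int(j), int(k)))
    return tris


def _triangle_weight(net: WeightedNetwork, t: tuple[int, int, int]) -> float:
    i, j, k = t
    w = net.weights
    return (w[i, j] + w[j, k] + w[i, k]) / 3.0


def enumerate_faces(
    net: WeightedNetwork, d: int = 5, mode: str = "chordal", dedupe_cycles: bool = False
) -> FaceSet:
    """Enumerate the 2-faces of order at most ``d``.

    ``d`` must be 3, 4 or 5: cost grows as O(n^d) and larger orders are
    rejected.  See the module docstring for the two modes.  In chordal mode
    ``dedupe_cycles`` keeps only the lexicographically smallest triangulation
    of each boundary cycle (sensitivity analysis; the default counts one face
    per triangulation).
    """
    if d not in VALID_ORDERS:
        raise ValueError(f"order d must be one of {VALID_ORDERS}, got {d}")
    if mode not in ("chordal", "all_cycles"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "all_cycles":
        return _enumerate_all_cycles(net, d)
    fs = _enumerate_chordal(net, d)
    if dedupe_cycles:
        best: dict[tuple[int, ...], Face2] = {}
        for f in fs.faces:
            cur = best.get(f.boundary)
            if cur is None or f.triangulation < cur.triangulation:
                best[f.boundary] = f
        fs = FaceSet(net, d, "chordal", sorted(best.values(), key=lambda f: (f.order, f.boundary)))
    return fs


def _enumerate_chordal(net: WeightedNetwork, d: int) -> FaceSet:
    tris = _triangles(net)
    tri_w = {t: _triangle_weight(net, t) for t in tris}
    faces = [Face2(t, (t,), tri_w[t]) for t in tris]

    # triangles indexed by each of their edges
    tri_by_edge: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
    for t in tris:
        i, j, k = t
        for e in ((i, j), (i, k), (j, k)):
            tri_by_edge.setdefault(e, []).append(t)

    if d >= 4:
        # order-4 face: two triangles glued along a shared edge (the chord),
        # boundary x-a-y-b where the chord is {a, b} and x, y are the apexes
        for chord, ts in tri_by_edge.items():
            a, b = chord
            for t1, t2 in combinations(ts, 2):
                x = next(v for v in t1 if v not in chord)
                y = next(v for v in t2 if v not in chord)
                boundary = _canonical_cycle((x, a, y, b))
                faces.append(Face2(boundary, tuple(sorted((t1, t2))), tri_w[t1] + tri_w[t2]))

    if d >= 5:
        # order-5 face: triangle path t1-t2-t3 glued along two distinct edges
        # of the middle triangle t2 = {p, q, r}; with chords {p,q} and {q,r}
        # the boundary is the 5-cycle a-p-r-b-q (a, b the outer apexes)
        for t2 in tris:
            edges = [tuple(sorted(pr)) for pr in combinations(t2, 2)]
            for c1, c2 in combinations(edges, 2):
                q = next(v for v in c1 if v in c2)  # shared node of the two chords
                p = next(v for v in c1 if v != q)
                r = next(v for v in c2 if v != q)
                for t1 in tri_by_edge[c1]:
                    if t1 == t2:
                        continue
                    a = next(v for v in t1 if v not in c1)
                    if a == r:
                        continue
                    for t3 in tri_by_edge[c2]:
                        if t3 == t2:
                            continue
                        b = next(v for v in t3 if v not in c2)
                        if b == p or b == a:
                            continue
                        boundary = _canonical_cycle((a, p, r, b, q))
                        tri_set = tuple(sorted((t1, t2, t3)))
                        faces.append(
                            Face2(boundary, tri_set, tri_w[t1] + tri_w[t2] + tri_w[t3])
                        )
    return FaceSet(net, d, "chordal", faces)


def _enumerate_all_cycles(net: WeightedNetwork, d: int) -> FaceSet:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    w = net.weights
    iu, iv = np.nonzero(np.triu(w, 1) > 0)
    g.add_edges_from(zip(iu.tolist(), iv.tolist()))
    faces = []
    for cyc in nx.simple_cycles(g, length_bound=d):
        boundary = _canonical_cycle(cyc)
        edge_ws = [w[boundary[i], boundary[(i + 1) % len(boundary)]] for i in range(len(boundary))]
        weight = float(np.mean(edge_ws))
        tri = (tuple(sorted(boundary)),) if len(boundary) == 3 else ()
        faces.append(Face2(boundary, tri, weight))
    faces.sort(key=lambda f: (f.order, f.boundary, f.triangulation))
    return FaceSet(net, d, "all_cycles", faces)


def hanging_edges(net: WeightedNetwork, e: tuple[str, str], d: int = 5) -> set[tuple[str, str]]:
    """Edges adjacent to ``e`` that lie on no simple cycle of <= d edges through ``e``.

    An adjacent edge e' = {v, x} (sharing endpoint v with e = {u, v}) hangs
    iff there is no simple path from x to u of at most ``d - 2`` edges
    avoiding v; such a path would close a cycle of length <= d containing
    both edges.
    """
    u, v = (net.index(x) for x in e)
    if net.weights[u, v] <= 0:
        raise KeyError(f"edge {e} not present")
    out: set[tuple[str, str]] = set()
    for a, b in ((u, v), (v, u)):
        # adjacent edges through endpoint a, other endpoint x != b
        for x in net.neighbors(a):
            x = int(x)
            if x == b:
                continue
            if not _path_exists(net, x, b, d - 2, forbidden={a}):
                out.add(tuple(sorted((net.labels[a], net.labels[x]))))
    return out


def _path_exists(net: WeightedNetwork, src: int, dst: int, max_edges: int, forbidden: set[int]) -> bool:
    """Is there a simple path src -> dst of at most ``max_edges`` edges avoiding ``forbidden``?"""
    if max_edges <= 0:
        return False
    stack = [(src, 0, {src})]
    while stack:
        node, depth, visited = stack.pop()
        for nb in net.neighbors(node):
            nb = int(nb)
            if nb == dst:
                return True
            if depth + 1 < max_edges and nb not in forbidden and nb not in visited:
                stack.append((nb, depth + 1, visited | {nb}))
    return False


def parallel_pairs(
    net: WeightedNetwork,
    e: tuple[str, str],
    faces: FaceSet,
    formula: str = "eq2",
):
    """Edges parallel to ``e`` in the face partial order.

    Two edges are parallel iff they share a common immediate predecessor
    (an endpoint) or a common immediate successor (a 2-face having both as
    boundary edges) — but not both.

    ``formula="eq2"`` restricts to parallel edges sharing a face with ``e``
    (the simplified curvature's sum runs over face-mates only; two disjoint
    boundary edges of one face never share an endpoint) and yields
    ``(edge_labels, face)`` pairs, one per (edge, face) incidence.
    ``formula="eq1"`` applies the full shared-endpoint XOR shared-face rule
    and yields ``(edge_labels, None)`` once per qualifying edge.
    """
    if faces.net is not net:
        raise ValueError("face set was enumerated on a different network")
    u, v = (net.index(x) for x in e)
    if u > v:
        u, v = v, u
    if formula == "eq2":
        out = []
        for f in faces.faces_with_edge(u, v):
            for a, b in f.boundary_edges():
                if a not in (u, v) and b not in (u, v):
                    out.append(((net.labels[a], net.labels[b]), f))
        return out
    if formula != "eq1":
        raise ValueError(f"unknown formula {formula!r}")

    face_mates: set[tuple[int, int]] = set()
    for f in faces.faces_with_edge(u, v):
        for ed in f.boundary_edges():
            if ed != (u, v):
                face_mates.add(ed)
    node_mates: set[tuple[int, int]] = set()
    for a, b in ((u, v), (v, u)):
        for x in net.neighbors(a):
            x = int(x)
            if x != b:
                node_mates.add(tuple(sorted((a, x))))
    par = node_mates.symmetric_difference(face_mates)
    return [((net.labels[a], net.labels[b]), None) for a, b in sorted(par)]


def sequence_count(n: int, d: int) -> int:
    """Number of ordered sequences of 1..(d-3) distinct nodes from an (n-3)-node pool.

    This counts the candidate interior-node sequences of a short path that
    would close a cycle of length <= d through a fixed edge and an adjacent
    edge: sum_{j=1}^{d-3} C(n-3, j) * j!.  Its rapid growth with n is why
    hanging edges are rare in dense networks.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if d < 4:
        raise ValueError(f"d must be >= 4, got {d}")
    return sum(math.comb(n - 3, j) * math.factorial(j) for j in range(1, d - 2))
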