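"""Curvature tests, anchored by an independent brute-force implementation.

The oracle below enumerates glued-triangle faces by scanning all node
triples and all unordered pairs/triples of triangles, then evaluates the
simplified curvature formula literally, term by term.  It shares no code
with the optimized enumeration in :mod:`netcurv.complexes`.
"""

import math
from itertools import combinations

import numpy as np
import pytest

from netcurv import (
    SynthSpec,
    WeightedNetwork,
    curvature_map,
    edge_curvature_local,
    enumerate_faces,
    fixture,
    forman_curvature,
    forman_curvature_full,
    prop1_check,
    random_weighted_network,
)
from netcurv.synth import reweight

from conftest import make_net

# ---------------------------------------------------------------- oracle


def _oracle_faces(w: np.ndarray, d: int):
    """(frozenset boundary edges, weight) of every glued-triangle face, naively."""
    n = w.shape[0]
    tris = [t for t in combinations(range(n), 3) if all(w[a, b] > 0 for a, b in combinations(t, 2))]
    t_w = {t: (w[t[0], t[1]] + w[t[0], t[2]] + w[t[1], t[2]]) / 3 for t in tris}
    t_e = {t: {frozenset(e) for e in combinations(t, 2)} for t in tris}
    faces = [(t_e[t], t_w[t]) for t in tris]
    if d >= 4:
        for t1, t2 in combinations(tris, 2):
            shared = t_e[t1] & t_e[t2]
            if len(shared) == 1 and len(set(t1) | set(t2)) == 4:
                faces.append(((t_e[t1] | t_e[t2]) - shared, t_w[t1] + t_w[t2]))
    if d >= 5:
        for trip in combinations(tris, 3):
            for mid in trip:
                ends = [t for t in trip if t != mid]
                s1 = t_e[ends[0]] & t_e[mid]
                s2 = t_e[ends[1]] & t_e[mid]
                if (
                    len(s1) == 1
                    and len(s2) == 1
                    and s1 != s2
                    and len(t_e[ends[0]] & t_e[ends[1]]) == 0
                    and len(set(trip[0]) | set(trip[1]) | set(trip[2])) == 5
                ):
                    boundary = (t_e[ends[0]] | t_e[mid] | t_e[ends[1]]) - s1 - s2
                    faces.append((boundary, t_w[ends[0]] + t_w[mid] + t_w[ends[1]]))
    return faces


def oracle_curvature(w: np.ndarray, i: int, j: int, d: int) -> float:
    """Literal simplified-formula evaluation from the naive face list."""
    we = w[i, j]
    if we == 0:
        return 0.0
    faces = [(b, fw) for b, fw in _oracle_faces(w, d) if frozenset((i, j)) in b]
    term_faces = sum(we / fw for _, fw in faces)
    nw = []
    for v in (i, j):
        inc = [w[v, x] for x in range(w.shape[0]) if w[v, x] > 0]
        nw.append(sum(inc) / len(inc))
    term_nodes = sum(nw) / we
    term_par = 0.0
    for b, fw in faces:
        for e2 in b:
            if not (e2 & {i, j}):
                a, c = tuple(e2)
                term_par += math.sqrt(we * w[a, c]) / fw
    return we * (term_faces + term_nodes - term_par)


def _connected_atlas_graphs(max_nodes=6):
    import networkx as nx

    for g in nx.graph_atlas_g()[1:]:
        if 2 <= g.number_of_nodes() <= max_nodes and nx.is_connected(g):
            yield g


def _net_from_adjacency(w):
    from netcurv.netio import default_labels

    return WeightedNetwork(default_labels(w.shape[0]), w)


# ----------------------------------------------------------------- tests


class TestHandValues:
    def test_unit_triangle(self, k3):
        for u, v, _ in k3.edges():
            assert forman_curvature(k3, (u, v)) == pytest.approx(3.0)
            assert forman_curvature_full(k3, (u, v)) == pytest.approx(3.0)

    def test_isolated_edge(self):
        net = make_net("ab", [("a", "b", 0.5)])
        assert forman_curvature(net, ("a", "b")) == pytest.approx(1.0)

    def test_zero_weight_pair_is_zero(self):
        net = make_net("abc", [("a", "b", 0.5)])
        assert forman_curvature(net, ("a", "c")) == 0.0

    def test_chorded_c4_rim_and_chord(self, chorded_c4):
        rim = forman_curvature(chorded_c4, ("n000", "n001"), d=4)
        chord = forman_curvature(chorded_c4, ("n000", "n002"), d=4)
        assert rim == pytest.approx(3.0)
        assert chord == pytest.approx(4.0)

    def test_star_full_vs_simplified(self, star13):
        center = star13.labels[max(range(4), key=star13.degree)]
        leaf = sorted(l for l in star13.labels if l != center)[0]
        faces = enumerate_faces(star13, d=5, mode="all_cycles")
        assert forman_curvature_full(star13, (center, leaf), faces=faces) == pytest.approx(0.0)
        assert forman_curvature(star13, (center, leaf), faces=faces) == pytest.approx(2.0)

    def test_k22_all_cycles(self):
        net = fixture("K22")
        faces = enumerate_faces(net, d=4, mode="all_cycles")
        for u, v, _ in net.edges():
            assert forman_curvature_full(net, (u, v), d=4, faces=faces) == pytest.approx(2.0)
            assert forman_curvature(net, (u, v), d=4, faces=faces) == pytest.approx(2.0)


class TestOracleEquivalence:
    def test_all_small_connected_unit_graphs(self):
        count = 0
        for g in _connected_atlas_graphs(6):
            n = g.number_of_nodes()
            w = np.zeros((n, n))
            nodes = sorted(g.nodes())
            for a, b in g.edges():
                i, j = nodes.index(a), nodes.index(b)
                w[i, j] = w[j, i] = 1.0
            net = _net_from_adjacency(w)
            table = curvature_map(net, d=5, mode="chordal")
            for (u, v), got in table.values.items():
                want = oracle_curvature(w, net.index(u), net.index(v), 5)
                assert got == pytest.approx(want, abs=1e-9), f"n={n} edge={u},{v}"
            count += 1
        assert count >= 100  # all connected graphs on <= 6 nodes

    @pytest.mark.parametrize("seed", range(50))
    def test_random_weighted_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        net = random_weighted_network(SynthSpec(n=n, p=0.35, seed=seed))
        w = net.weights
        table = curvature_map(net, d=5, mode="chordal")
        for (u, v), got in table.values.items():
            want = oracle_curvature(w, net.index(u), net.index(v), 5)
            assert got == pytest.approx(want, abs=1e-9)


class TestCurvatureTable:
    def test_triangle_map(self, k3):
        table = curvature_map(k3)
        assert len(table) == 3
        assert all(c == pytest.approx(3.0) for c in table.values.values())

    def test_symmetric_lookup_and_absent_zero(self, k3):
        table = curvature_map(k3)
        assert table.value("n001", "n000") == table.value("n000", "n001")
        assert table.value("n000", "zzz") == 0.0

    def test_empty_graph_empty_table(self):
        net = make_net("abc", [])
        assert len(curvature_map(net)) == 0

    def test_local_equals_global(self):
        net = random_weighted_network(SynthSpec(n=15, p=0.3, seed=11))
        table = curvature_map(net, d=5)
        for u, v, _ in net.edges():
            assert edge_curvature_local(net, (u, v), d=5) == pytest.approx(
                table.value(u, v), abs=1e-9
            )


class TestProposition1:
    """Full and simplified formulas coincide exactly when no edge hangs."""

    @pytest.mark.parametrize("name", ["Q3", "Q4", "K22", "K33", "K222"])
    @pytest.mark.parametrize("d", [4, 5])
    def test_hanging_free_classes(self, name, d):
        net0 = fixture(name)
        n_weightings = 3 if name == "Q4" else 5
        for seed in range(n_weightings):
            net = reweight(net0, seed=seed)
            for u, v, _ in net.edges():
                res = prop1_check(net, (u, v), d)
                assert not res.has_hanging
                assert res.equal, (name, d, seed, u, v)

    def test_star_exhibits_inequality(self, star13):
        center = star13.labels[max(range(4), key=star13.degree)]
        leaf = sorted(l for l in star13.labels if l != center)[0]
        res = prop1_check(star13, (center, leaf), d=5)
        assert res.has_hanging
        assert res.eq1 == pytest.approx(0.0)
        assert res.eq2 == pytest.approx(2.0)
        assert not res.equal

    def test_equality_invariant_under_face_weight_rescaling(self):
        # the agreement of the two formulas does not depend on face weights
        net = reweight(fixture("K222"), seed=9)
        faces = enumerate_faces(net, d=5, mode="all_cycles")
        for scale in (0.1, 7.3):
            scaled = [f.__class__(f.boundary, f.triangulation, f.weight * scale) for f in faces.faces]
            fs = faces.__class__(net, 5, "all_cycles", scaled)
            for u, v, _ in net.edges():
                eq1 = forman_curvature_full(net, (u, v), 5, faces=fs)
                eq2 = forman_curvature(net, (u, v), 5, faces=fs)
                assert eq1 == pytest.approx(eq2, abs=1e-9)


class TestInvariances:
    def test_value_symmetric_in_arguments(self):
        net = random_weighted_network(SynthSpec(n=10, p=0.4, seed=3))
        for u, v, _ in net.edges():
            assert forman_curvature(net, (u, v)) == forman_curvature(net, (v, u))

    def test_global_weight_rescaling_recomputed(self):
        # node, edge and face weights all scale by c, so recomputing under
        # c*w must reproduce c*curvature (degree-1 homogeneity)
        net = random_weighted_network(SynthSpec(n=8, p=0.5, seed=1))
        scaled = WeightedNetwork(net.labels, 0.5 * net.weights)
        t1 = curvature_map(net, d=5)
        t2 = curvature_map(scaled, d=5)
        for e, c in t1.values.items():
            assert t2.values[e] == pytest.approx(0.5 * c, abs=1e-9)
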