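"""Null-model significance of curvature differences via degree-preserving rewiring.

The null model is the classical Markov-chain double-edge-swap: pick two
edges {a, b} and {c, d} with four distinct endpoints, rewire them to
{a, d} and {c, b}, reject the proposal if it would create a self-loop, a
duplicate edge, or create/destroy the pinned node pair under test.  Each
edge carries its weight along, so the degree sequence and the multiset of
edge weights are preserved exactly (node strength is not; see docs).  The
chain runs until ``n_swaps`` proposals have been *accepted* (default five
times the edge count), with a proposal cap so rigid graphs terminate.

For an edge e with observed Delta_e, the null ensemble re-evaluates the
curvature difference at e on R independent randomization pairs of the two
input networks and summarizes the result as a standard z-score; |z| >= 2 is
the conventional significance label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forman import edge_curvature_local
from .netio import WeightedNetwork

logger = logging.getLogger(__name__)

SWAP_FACTOR_DEFAULT = 5
PROPOSAL_CAP_FACTOR = 100
Z_SIGNIFICANT = 2.0


@dataclass
class NullEnsembleResult:
    edge: tuple[str, str]
    observed_delta: float
    samples: np.ndarray
    z: float | None
    seed: int
    swaps_performed: int

    @property
    def significant(self) -> bool:
        return self.z is not None and abs(self.z) >= Z_SIGNIFICANT


def _has_two_independent_edges(edges: list) -> bool:
    for i in range(len(edges)):
        a, b = edges[i][0], edges[i][1]
        for j in range(i + 1, len(edges)):
            c, d = edges[j][0], edges[j][1]
            if len({a, b, c, d}) == 4:
                return True
    return False


def edge_swap_randomize(
    net: WeightedNetwork,
    pinned: tuple[str, str],
    n_swaps: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> WeightedNetwork:
    """Degree-preserving randomization keeping the pinned pair's status fixed.

    If the pinned pair {u, v} is an edge it survives with its weight; if it
    is not, no swap may create it.  ``n_swaps`` counts accepted swaps
    (default ``5 * |E|``); proposals are capped at 100x that to guarantee
    termination on rigid graphs.
    """
    net_out, _ = _randomize_with_count(net, pinned, n_swaps, seed)
    return net_out


def _randomize_with_count(net, pinned, n_swaps, seed):
    pu, pv = (net.index(x) for x in pinned)
    pin = (min(pu, pv), max(pu, pv))
    edges = [[i, j, w] for i, j, w in _index_edges(net)]
    m = len(edges)
    if n_swaps is None:
        n_swaps = SWAP_FACTOR_DEFAULT * m
    if n_swaps == 0:
        return WeightedNetwork(net.labels, net.weights.copy()), 0
    if m < 2 or not _has_two_independent_edges(edges):
        logger.warning("graph has no two independent edges; returning it unchanged")
        return WeightedNetwork(net.labels, net.weights.copy()), 0

    rng = np.random.default_rng(seed)
    edge_set = {(e[0], e[1]) for e in edges}
    accepted = 0
    proposals = 0
    cap = PROPOSAL_CAP_FACTOR * n_swaps
    while accepted < n_swaps and proposals < cap:
        proposals += 1
        i1, i2 = rng.integers(0, m, size=2)
        if i1 == i2:
            continue
        a, b, w1 = edges[i1]
        c, d, w2 = edges[i2]
        if rng.integers(2):
            a, b = b, a
        if rng.integers(2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        e_old1, e_old2 = (min(a, b), max(a, b)), (min(c, d), max(c, d))
        e_new1, e_new2 = (min(a, d), max(a, d)), (min(c, b), max(c, b))
        if e_new1 in edge_set or e_new2 in edge_set:
            continue
        if pin in (e_old1, e_old2) or pin in (e_new1, e_new2):
            continue
        edge_set.remove(e_old1)
        edge_set.remove(e_old2)
        edge_set.add(e_new1)
        edge_set.add(e_new2)
        # weights travel with the rewired pairing: w({a,d}) := w({a,b})
        edges[i1] = [e_new1[0], e_new1[1], w1]
        edges[i2] = [e_new2[0], e_new2[1], w2]
        accepted += 1

    w = np.zeros_like(net.weights)
    for i, j, wt in edges:
        w[i, j] = wt
        w[j, i] = wt
    return WeightedNetwork(net.labels, w), accepted


def _index_edges(net: WeightedNetwork):
    iu, iv = np.nonzero(np.triu(net.weights, 1) > 0)
    for i, j in zip(iu.tolist(), iv.tolist()):
        yield i, j, float(net.weights[i, j])


def z_score(observed: float, samples) -> float | None:
    """Standard z-score of ``observed`` against a null sample (population std).

    Returns ``None`` (undefined) when the sample has zero variance.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("z_score requires at least 2 null samples")
    std = samples.std()
    if std == 0:
        return None
    return float((observed - samples.mean()) / std)


def replicate_deltas(
    net1: WeightedNetwork,
    net2: WeightedNetwork,
    e: tuple[str, str],
    d: int = 5,
    mode: str = "chordal",
    R: int = 100,
    n_swaps: int | None = None,
    seed: int = 0,
) -> NullEnsembleResult:
    """Null ensemble of curvature differences at edge ``e`` with its z-score.

    Each of the R replicates independently randomizes both networks (pinned
    at e's endpoints) and evaluates the curvature difference at e.
    Deterministic given ``seed``: per-replicate streams are spawned from a
    single root seed sequence, so replicates are independent and the result
    is reproducible.
    """
    if R < 2:
        raise ValueError("need at least R=2 replicates")
    observed = edge_curvature_local(net1, e, d, mode) - edge_curvature_local(net2, e, d, mode)
    root = np.random.SeedSequence(seed)
    children = root.spawn(2 * R)
    samples = np.empty(R)
    total_swaps = 0
    for j in range(R):
        g1, s1 = _randomize_with_count(net1, e, n_swaps, children[2 * j])
        g2, s2 = _randomize_with_count(net2, e, n_swaps, children[2 * j + 1])
        total_swaps += s1 + s2
        samples[j] = edge_curvature_local(g1, e, d, mode) - edge_curvature_local(g2, e, d, mode)
    return NullEnsembleResult(
        edge=tuple(e),
        observed_delta=observed,
        samples=samples,
        z=z_score(observed, samples),
        seed=seed,
        swaps_performed=total_swaps,
    )
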