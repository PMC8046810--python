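"""Synthetic networks emulating thresholded functional-correlation data.

Thresholded correlation networks are symmetric, zero-diagonal, and carry
edge weights in [0.4, 1): correlations below the 0.4 sparsification
threshold have been zeroed, so surviving weights start there.  The
generator draws Erdos-Renyi G(n, p) topology with i.i.d. uniform weights in
that band, which puts synthetic data in the same post-threshold regime the
curvature pipeline runs in on real connectomes.

:func:`planted_pair` builds (control, disease) pairs with a localized
perturbation around one target edge: incident edge weights rescaled and a
few triangle-closing edges added through the target, which changes the
target's 2-face set — the regime where curvature differences respond but
plain edge-weight differences barely move.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .netio import WeightedNetwork, default_labels


@dataclass(frozen=True)
class Perturbation:
    """Localized change applied to the disease copy of a synthetic pair.

    ``target``: edge (label pair) at the center, or None to pick one (see
    :func:`planted_pair` for the selection rule).  ``effect``:
    multiplicative factor on the target edge's weight (clamped to the weight
    band).  ``k_close``: number of triangles closed through the target.
    ``radius``: hop radius of the perturbed neighborhood; only the
    radius-1 perturbation (spokes attached directly to the target's
    endpoints) is implemented.
    """

    target: tuple[str, str] | None = None
    effect: float = 1.5
    radius: int = 1
    k_close: int = 3

    def __post_init__(self):
        if self.radius != 1:
            raise NotImplementedError("only radius-1 perturbations are supported")


@dataclass(frozen=True)
class SynthSpec:
    n: int
    p: float
    weight_low: float = 0.4
    weight_high: float = 1.0
    seed: int = 0
    perturbation: Perturbation | None = None

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError(f"edge density p must be in [0, 1], got {self.p}")
        if not 0 <= self.weight_low < self.weight_high <= 1:
            raise ValueError("need 0 <= weight_low < weight_high <= 1")


def random_weighted_network(spec: SynthSpec) -> WeightedNetwork:
    """G(n, p) with i.i.d. uniform weights in [weight_low, weight_high); seeded."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    present = rng.random(len(iu[0])) < spec.p
    weights = rng.uniform(spec.weight_low, spec.weight_high, len(iu[0]))
    w[iu] = np.where(present, weights, 0.0)
    w = w + w.T
    return WeightedNetwork(default_labels(n), w)


class PlantedPair(NamedTuple):
    control: WeightedNetwork
    disease: WeightedNetwork
    target: tuple[str, str]


def planted_pair(spec: SynthSpec) -> PlantedPair:
    """A (control, disease) pair with a face-level perturbation at one edge.

    The disease network is the control with the target edge's weight
    multiplied by ``effect`` (clamped into the weight band) and up to
    ``k_close`` new triangles closed through the target: each closure picks a
    node not yet adjacent to either endpoint and adds both spoke edges, with
    light weights at the bottom of the band so the planted triangles weigh
    little and the target's face term responds strongly.  With
    ``effect == 1`` and ``k_close == 0`` the pair is identical.

    The perturbation is deliberately *local in the 2-complex*: when the
    target is chosen at random it is drawn from the edges with the fewest
    existing triangles, and closure nodes are preferred whose neighborhoods
    avoid the target's radius-1 neighborhood and each other, so the new faces
    incident to the target are exactly the planted triangles.  The target's
    curvature then shifts by the planted face terms while its edge weight
    barely moves — curvature flags the anomaly where the plain weight
    difference stays blind.  Returns (control, disease, target).
    """
    if spec.perturbation is None:
        raise ValueError("planted_pair requires spec.perturbation")
    pert = spec.perturbation
    control = random_weighted_network(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9E3779B9]))
    w0 = control.weights
    n = control.n_nodes
    nbr = [set(np.nonzero(w0[i] > 0)[0].tolist()) for i in range(n)]

    def clean_closures(i: int, j: int) -> int:
        ball = (nbr[i] | nbr[j]) - {i, j}
        return sum(
            1
            for x in range(n)
            if x not in (i, j) and w0[i, x] == 0 and w0[j, x] == 0 and not (nbr[x] & ball)
        )

    if pert.target is None:
        edges = [(control.index(u), control.index(v)) for u, v, _ in control.edges()]
        if not edges:
            raise ValueError("control network has no edges to perturb")
        # least-embedded edges first, then most room for clean closures
        n_tri = [len(nbr[i] & nbr[j]) for i, j in edges]
        pool = [e for e, t in zip(edges, n_tri) if t == min(n_tri)]
        scores = [clean_closures(i, j) for i, j in pool]
        pool = [e for e, s in zip(pool, scores) if s == max(scores)]
        ti, tj = pool[int(rng.integers(len(pool)))]
        target = (control.labels[ti], control.labels[tj])
    else:
        target = tuple(pert.target)
        if not control.has_edge(*target):
            raise ValueError(f"target edge {target} absent from control network")
        ti, tj = (control.index(x) for x in target)

    w = w0.copy()
    hi = np.nextafter(1.0, 0.0)
    w[ti, tj] = w[tj, ti] = float(np.clip(w[ti, tj] * pert.effect, spec.weight_low, hi))

    ball = (nbr[ti] | nbr[tj]) - {ti, tj}
    cands = [x for x in range(n) if x not in (ti, tj) and w0[ti, x] == 0 and w0[tj, x] == 0]
    order = rng.permutation(len(cands))
    cands = sorted((cands[k] for k in order), key=lambda x: len(nbr[x] & ball))
    picked: list[int] = []
    for x in cands:
        if len(picked) == pert.k_close:
            break
        if any(w0[x, y] > 0 for y in picked):
            continue
        picked.append(x)
    lo, span = spec.weight_low, min(0.1, spec.weight_high - spec.weight_low)
    for x in picked:
        w[ti, x] = w[x, ti] = rng.uniform(lo, lo + span)
        w[tj, x] = w[x, tj] = rng.uniform(lo, lo + span)

    return PlantedPair(control, WeightedNetwork(control.labels, w), tuple(target))


def _from_networkx(g) -> WeightedNetwork:
    nodes = sorted(g.nodes(), key=str)
    labels = default_labels(len(nodes))
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for u, v in g.edges():
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = 1.0
    return WeightedNetwork(labels, w)


FIXTURE_NAMES = (
    "K3",
    "K4",
    "star13",
    "chorded_C4",
    "double_star",
    "Q3",
    "Q4",
    "K22",
    "K33",
    "K222",
)


def fixture(name: str) -> WeightedNetwork:
    """Named unit-weight test graph.

    ``star13`` is the 3-leaf star (every leaf edge hangs off every other),
    ``chorded_C4`` the 4-cycle with one chord (the smallest graph with a
    glued order-4 face), ``double_star`` two 2-leaf stars joined by a bridge
    (negative Ollivier, positive Forman), ``Q3``/``Q4`` hypercubes and
    ``K22``/``K33``/``K222`` complete multipartite graphs (hanging-edge-free
    classes for d >= 4).
    """
    import networkx as nx

    if name == "K3":
        return _from_networkx(nx.complete_graph(3))
    if name == "K4":
        return _from_networkx(nx.complete_graph(4))
    if name == "star13":
        return _from_networkx(nx.star_graph(3))
    if name == "chorded_C4":
        g = nx.cycle_graph(4)
        g.add_edge(0, 2)
        return _from_networkx(g)
    if name == "double_star":
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)])
        return _from_networkx(g)
    if name == "Q3":
        return _from_networkx(nx.hypercube_graph(3))
    if name == "Q4":
        return _from_networkx(nx.hypercube_graph(4))
    if name == "K22":
        return _from_networkx(nx.complete_multipartite_graph(2, 2))
    if name == "K33":
        return _from_networkx(nx.complete_multipartite_graph(3, 3))
    if name == "K222":
        return _from_networkx(nx.complete_multipartite_graph(2, 2, 2))
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def reweight(net: WeightedNetwork, low: float = 0.4, high: float = 1.0, seed: int = 0) -> WeightedNetwork:
    """Replace unit weights with random uniform weights in [low, high); keeps topology."""
    rng = np.random.default_rng(seed)
    w = np.zeros_like(net.weights)
    iu, iv = np.nonzero(np.triu(net.weights, 1) > 0)
    for i, j in zip(iu.tolist(), iv.tolist()):
        w[i, j] = w[j, i] = rng.uniform(low, high)
    return WeightedNetwork(net.labels, w)
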