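"""Ollivier-Ricci edge curvature, for sign comparison with the Forman variant.

The curvature of an edge e = {u, v} is kappa(e) = 1 - W1(m_u, m_v), where
m_x places uniform mass 1/deg(x) on each neighbor of x (zero idleness) and
W1 is the L1 Wasserstein (optimal transport) distance under the hop-count
ground metric.  With this classical variant kappa lies in [-2, 1] on any
graph.  W1 is solved as an exact small linear program; exactness matters
because sign determination near zero is the point of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .netio import WeightedNetwork


@dataclass(frozen=True)
class NeighborDistribution:
    """Uniform probability mass on the neighborhood of a center node."""

    center: str
    support: dict[str, float]

    def __post_init__(self):
        total = sum(self.support.values())
        if abs(total - 1.0) > 1e-12 or any(m < 0 for m in self.support.values()):
            raise ValueError("masses must be non-negative and sum to 1")


def neighbor_distribution(net: WeightedNetwork, v: str) -> NeighborDistribution:
    i = net.index(v)
    nbrs = net.neighbors(i)
    if len(nbrs) == 0:
        raise ValueError(f"node {v!r} is isolated: no neighbor distribution")
    mass = 1.0 / len(nbrs)
    return NeighborDistribution(v, {net.labels[int(j)]: mass for j in nbrs})


def _hop_distances(net: WeightedNetwork, sources: list[int]) -> dict[int, dict[int, int]]:
    """BFS hop distances from each source node (unweighted)."""
    out = {}
    for s in sources:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for x in frontier:
                for y in net.neighbors(x):
                    y = int(y)
                    if y not in dist:
                        dist[y] = dist[x] + 1
                        nxt.append(y)
            frontier = nxt
        out[s] = dist
    return out


def wasserstein1(
    net: WeightedNetwork, mu: NeighborDistribution, nu: NeighborDistribution
) -> float:
    """Exact L1 optimal-transport distance between two node distributions.

    Solved as the transportation linear program with hop-count costs; the LP
    optimum is certified by solver status.  Raises if some mass of ``mu``
    cannot reach the support of ``nu`` (disconnected components).
    """
    src = [net.index(x) for x in mu.support]
    dst = [net.index(x) for x in nu.support]
    dists = _hop_distances(net, src)
    cost = np.empty((len(src), len(dst)))
    for a, s in enumerate(src):
        for b, t in enumerate(dst):
            if t not in dists[s]:
                raise ValueError("distributions live on disconnected components")
            cost[a, b] = dists[s][t]

    m, n = cost.shape
    a_eq = []
    b_eq = []
    for a in range(m):  # row sums = mu
        row = np.zeros(m * n)
        row[a * n : (a + 1) * n] = 1.0
        a_eq.append(row)
        b_eq.append(mu.support[net.labels[src[a]]])
    for b in range(n):  # column sums = nu
        col = np.zeros(m * n)
        col[b::n] = 1.0
        a_eq.append(col)
        b_eq.append(nu.support[net.labels[dst[b]]])
    res = linprog(cost.ravel(), A_eq=np.array(a_eq), b_eq=np.array(b_eq), method="highs")
    if res.status != 0:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def ollivier_curvature(net: WeightedNetwork, e: tuple[str, str]) -> float:
    """kappa(e) = 1 - W1(m_u, m_v) for an existing edge (hop distance 1)."""
    u, v = e
    if not net.has_edge(u, v):
        raise KeyError(f"edge {e} not present")
    return 1.0 - wasserstein1(net, neighbor_distribution(net, u), neighbor_distribution(net, v))


def _sgn(x: float) -> int | None:
    """Sign with 0 mapped to None (undefined: zero curvature is flat)."""
    if x > 0:
        return 1
    if x < 0:
        return -1
    return None


@dataclass
class SignWitness:
    description: str
    net: WeightedNetwork = field(repr=False)
    edge: tuple[str, str]
    sign_forman: int
    sign_ollivier: int
    forman: float
    ollivier: float


def sign_disagreement_search(
    n_max: int = 8,
    d: int = 5,
    budget: int = 10_000,
    seed: int = 0,
    include_fixtures: bool = True,
) -> list[SignWitness]:
    """Search for edges realizing each (sgn Forman, sgn Ollivier) combination.

    Scans curated fixtures and then random weighted connected graphs with at
    most ``n_max`` nodes, recording one witness per realized sign pair (zero
    curvatures are skipped, their sign being undefined).  The two curvature
    notions are distinct discretizations and all four combinations exist for
    d >= 5; the search stops early once all four are witnessed.
    """
    if d < 5:
        raise ValueError("sign comparison requires order d >= 5")
    from .forman import curvature_map
    from .synth import SynthSpec, fixture, random_weighted_network

    found: dict[tuple[int, int], SignWitness] = {}

    def scan(net: WeightedNetwork, description: str) -> bool:
        table = curvature_map(net, d=min(d, 5), mode="chordal")
        for (u, v), cf in sorted(table.values.items()):
            sf = _sgn(cf)
            if sf is None:
                continue
            co = ollivier_curvature(net, (u, v))
            so = _sgn(co)
            if so is None or (sf, so) in found:
                continue
            found[(sf, so)] = SignWitness(description, net, (u, v), sf, so, cf, co)
            if len(found) == 4:
                return True
        return False

    if include_fixtures:
        for name in ("K3", "double_star"):
            if scan(fixture(name), f"fixture:{name}"):
                return sorted(found.values(), key=lambda w: (w.sign_forman, w.sign_ollivier))

    rng = np.random.default_rng(seed)
    for trial in range(budget):
        n = int(rng.integers(4, n_max + 1))
        p = float(rng.uniform(0.3, 0.95))
        net = random_weighted_network(
            SynthSpec(n=n, p=p, weight_low=0.1, weight_high=1.0, seed=int(rng.integers(2**31)))
        )
        if net.n_edges == 0:
            continue
        if scan(net, f"random:trial={trial},n={n}"):
            break
    return sorted(found.values(), key=lambda w: (w.sign_forman, w.sign_ollivier))
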