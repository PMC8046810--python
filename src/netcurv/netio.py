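"""Reading, writing and basic manipulation of weighted connectivity networks.

A network is a labeled undirected graph stored as a symmetric non-negative
weight matrix with a zero diagonal.  Functional-connectivity studies store
these as plain-text square matrices (one row per node) plus an optional
node-label file with one label per line; this module speaks that dialect.

An edge {u, v} exists iff its weight is strictly positive: setting a weight
to zero deletes the edge, raising it from zero creates one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Maximum tolerated |W - W.T| on ingest before a matrix is rejected.
SYMMETRY_TOL = 1e-9


class NetworkFormatError(ValueError):
    """Raised when an input matrix violates the connectivity-matrix contract."""


@dataclass(frozen=True)
class WeightedNetwork:
    """An undirected weighted graph on a fixed, labeled node set.

    Parameters
    ----------
    labels
        Unique node identifiers, in matrix row order.
    weights
        Symmetric ``n x n`` float array, zero diagonal, non-negative entries
        once thresholded (negative correlations may be present before
        :func:`sparsify` is applied).
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    _adj: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise NetworkFormatError("node labels must be unique")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkFormatError(f"non-square matrix with shape {w.shape}")
        if w.shape[0] != n:
            raise NetworkFormatError(
                f"label count {n} does not match matrix size {w.shape[0]}"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1) > 0))

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def edge_weight(self, u: str, v: str) -> float:
        return float(self.weights[self.index(u), self.index(v)])

    def has_edge(self, u: str, v: str) -> bool:
        return self.edge_weight(u, v) > 0

    def edges(self):
        """Yield ``(label_u, label_v, weight)`` for every existing edge, u < v in row order."""
        iu, iv = np.nonzero(np.triu(self.weights, 1) > 0)
        for i, j in zip(iu.tolist(), iv.tolist()):
            yield self.labels[i], self.labels[j], float(self.weights[i, j])

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted array of node indices adjacent to node index ``i`` (cached)."""
        if "nbrs" not in self._adj:
            w = self.weights
            self._adj["nbrs"] = [np.nonzero(w[k] > 0)[0] for k in range(self.n_nodes)]
        return self._adj["nbrs"][i]

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def degree_sequence(self) -> tuple[int, ...]:
        return tuple(int(np.count_nonzero(self.weights[k] > 0)) for k in range(self.n_nodes))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for u, v, w in self.edges():
            g.add_edge(u, v, weight=w)
        return g

    def validate(self) -> None:
        """Check symmetry, zero diagonal and non-negativity; raise on violation."""
        w = self.weights
        if not np.array_equal(w, w.T):
            raise NetworkFormatError("weight matrix is not symmetric")
        if np.any(np.diag(w) != 0):
            raise NetworkFormatError("weight matrix has non-zero diagonal")
        if np.any(w < 0):
            raise NetworkFormatError("weight matrix has negative entries")


def default_labels(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n - 1)))
    return tuple(f"n{i:0{width}d}" for i in range(n))


def _sniff_delimiter(path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    return "," if "," in first else None


def load_matrix(matrix_path, labels_path=None, symmetrize: bool = False) -> WeightedNetwork:
    """Load a connectivity matrix (whitespace- or comma-delimited) as a network.

    The matrix must be square and symmetric to within ``SYMMETRY_TOL``.  The
    diagonal (self-correlation) is zeroed: nodes carry no self-edges.  Negative
    entries are preserved here; thresholding (:func:`sparsify`) removes them.

    Parameters
    ----------
    matrix_path
        Plain-text square numeric matrix, no header.
    labels_path
        Optional file with one node label per line; must match the matrix
        size.  Defaults to generated labels ``n000, n001, ...``.
    symmetrize
        Average ``(W + W.T) / 2`` instead of rejecting asymmetric input.
        Off by default: malformed data should fail loudly.
    """
    delim = _sniff_delimiter(matrix_path)
    w = np.loadtxt(matrix_path, delimiter=delim, dtype=float, ndmin=2)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise NetworkFormatError(f"non-square matrix with shape {w.shape}")
    asym = np.max(np.abs(w - w.T)) if w.size else 0.0
    if asym > SYMMETRY_TOL and not symmetrize:
        raise NetworkFormatError(
            f"asymmetric matrix: max |w[i,j] - w[j,i]| = {asym:g} > {SYMMETRY_TOL:g}"
        )
    # enforce exact symmetry and a zero diagonal
    w = (w + w.T) / 2.0 if symmetrize else np.triu(w, 1) + np.triu(w, 1).T
    np.fill_diagonal(w, 0.0)
    if labels_path is not None:
        with open(labels_path) as fh:
            labels = tuple(line.strip() for line in fh if line.strip())
        if len(labels) != w.shape[0]:
            raise NetworkFormatError(
                f"label count {len(labels)} does not match matrix size {w.shape[0]}"
            )
    else:
        labels = default_labels(w.shape[0])
    return WeightedNetwork(labels, w)


def save_matrix(net: WeightedNetwork, matrix_path, labels_path=None) -> None:
    """Write the weight matrix (and optionally the labels) in the plain-text dialect."""
    np.savetxt(matrix_path, net.weights, fmt="%.17g", delimiter=" ")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for lab in net.labels:
                fh.write(lab + "\n")


def mean_network(nets: list[WeightedNetwork]) -> WeightedNetwork:
    """Element-wise arithmetic mean of the weight matrices of a cohort.

    All networks must share the same label ordering; used to build the
    cohort-mean connectivity matrix of a subject group.
    """
    if not nets:
        raise ValueError("mean_network requires at least one network")
    labels = nets[0].labels
    for net in nets[1:]:
        if net.labels != labels:
            raise NetworkFormatError("networks have mismatched node labels")
    w = np.mean([net.weights for net in nets], axis=0)
    return WeightedNetwork(labels, w)


def sparsify(net: WeightedNetwork, tau: float = 0.4) -> WeightedNetwork:
    """Zero out every entry strictly below the threshold ``tau``.

    Negative correlations are removed for any ``tau > 0``, so the result is a
    valid non-negative network.  Idempotent for fixed ``tau``.
    """
    if tau <= 0:
        logger.warning("sparsify called with tau=%g <= 0: only negatives are removed", tau)
    w = np.where(net.weights < tau, 0.0, net.weights)
    np.fill_diagonal(w, 0.0)
    out = WeightedNetwork(net.labels, w)
    logger.info("sparsify(tau=%g): %d of %d edges survive", tau, out.n_edges, net.n_edges)
    return out


ANOMALY_TABLE_HEADER = (
    "edge_u",
    "edge_v",
    "curv_control",
    "curv_disease",
    "delta",
    "norm_delta",
    "weight_delta",
    "z",
)


def write_anomaly_table(records, path) -> None:
    """Write per-edge anomaly records as a TSV, sorted by descending |delta|.

    ``records`` is an iterable of objects with attributes matching
    :data:`ANOMALY_TABLE_HEADER` (see :class:`netcurv.anomaly.AnomalyRecord`);
    ``z`` may be ``None`` and is written as ``NA``.  Ties in |delta| are broken
    lexicographically by label pair so the output is deterministic.
    """
    recs = sorted(records, key=lambda r: (-abs(r.delta), r.edge))
    with open(path, "w") as fh:
        fh.write("\t".join(ANOMALY_TABLE_HEADER) + "\n")
        for r in recs:
            z = "NA" if r.z is None else f"{r.z:.6g}"
            fh.write(
                f"{r.edge[0]}\t{r.edge[1]}\t{r.curv_control:.6f}\t{r.curv_disease:.6f}"
                f"\t{r.delta:.6f}\t{r.norm_delta:.6f}\t{r.weight_delta:.6f}\t{z}\n"
            )
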