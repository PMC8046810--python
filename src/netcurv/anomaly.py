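"""Curvature-based anomaly detection between two snapshots of a network.

Given per-edge curvature tables for a control network G1 and a disease (or
later-time) network G2 on the same node set, the anomaly statistic of an
edge is the curvature difference Delta_e = C_G1(e) - C_G2(e).  Edges whose
|Delta_e| exceeds a cutoff (by default twice the population standard
deviation of the Delta values) are flagged as outliers.  For comparison with
the naive edge-weight baseline Lambda_e = w1(e) - w2(e), which lives in
[-1, 1] for correlation weights, the Delta values are rescaled to [-1, 1]
with the linear map eta(Delta) = (2*Delta - high - low)/(high - low).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forman import CurvatureTable
from .netio import WeightedNetwork


@dataclass
class AnomalyRecord:
    """One edge's row in the anomaly report."""

    edge: tuple[str, str]
    curv_control: float
    curv_disease: float
    delta: float
    norm_delta: float
    weight_delta: float
    z: float | None = None


def delta_map(
    table1: CurvatureTable, table2: CurvatureTable, all_pairs: bool = False
) -> dict[tuple[str, str], float]:
    """Delta_e = C1(e) - C2(e) over the union of the two edge sets.

    Pairs absent from one table use that network's zero-curvature convention;
    pairs absent from both are zero in both and are omitted unless
    ``all_pairs`` is set (which includes every node pair, padding the map —
    and hence downstream summary statistics — with zeros).  Both tables must
    come from the same order/mode and label universe.
    """
    if (table1.d, table1.mode) != (table2.d, table2.mode):
        raise ValueError(
            f"curvature tables disagree on order/mode: "
            f"({table1.d},{table1.mode}) vs ({table2.d},{table2.mode})"
        )
    if table1.labels and table2.labels and set(table1.labels) != set(table2.labels):
        raise ValueError("curvature tables come from different label universes")
    edges = set(table1.edges()) | set(table2.edges())
    if all_pairs:
        labels = table1.labels or table2.labels
        if not labels:
            raise ValueError("all_pairs requires tables that carry their label universe")
        labels = sorted(labels)
        edges |= {
            (u, v) for i, u in enumerate(labels) for v in labels[i + 1 :]
        }
    return {e: table1.value(*e) - table2.value(*e) for e in sorted(edges)}


def summary_stats(deltas: dict, bins: int = 20):
    """Population mean, population std and a fixed-width histogram of the Delta values."""
    if not deltas:
        raise ValueError("summary_stats requires a non-empty delta map")
    vals = np.fromiter(deltas.values(), dtype=float)
    counts, edges = np.histogram(vals, bins=bins)
    return float(vals.mean()), float(vals.std()), (counts, edges)


def outlier_edges(deltas: dict, cutoff: float | str = "auto") -> list[tuple[str, str]]:
    """Edges with |Delta| above the cutoff, sorted by descending |Delta|.

    ``cutoff="auto"`` uses twice the population standard deviation of the
    Delta values.  Ties are broken lexicographically by label pair.
    """
    if cutoff == "auto":
        _, std, _ = summary_stats(deltas)
        cutoff = 2.0 * std
    cutoff = float(cutoff)
    hits = [e for e, dv in deltas.items() if abs(dv) > cutoff]
    return sorted(hits, key=lambda e: (-abs(deltas[e]), e))


def normalize_deltas(deltas: dict) -> dict[tuple[str, str], float]:
    """Linear rescaling of Delta values onto [-1, 1] (max -> 1, min -> -1).

    A constant delta map has no scale and maps to all zeros.
    """
    if not deltas:
        raise ValueError("normalize_deltas requires a non-empty delta map")
    vals = list(deltas.values())
    high, low = max(vals), min(vals)
    if high == low:
        return {e: 0.0 for e in deltas}
    return {e: (2.0 * dv - high - low) / (high - low) for e, dv in deltas.items()}


def weight_delta(net1: WeightedNetwork, net2: WeightedNetwork, e: tuple[str, str]) -> float:
    """Edge-weight difference Lambda_e = w1(e) - w2(e); absent edges weigh 0."""
    if set(net1.labels) != set(net2.labels):
        raise ValueError("networks have different label universes")
    return net1.edge_weight(*e) - net2.edge_weight(*e)


def build_records(
    net1: WeightedNetwork,
    net2: WeightedNetwork,
    table1: CurvatureTable,
    table2: CurvatureTable,
    edges=None,
    z_scores: dict | None = None,
) -> list[AnomalyRecord]:
    """Assemble :class:`AnomalyRecord` rows for the given edges (default: outliers)."""
    deltas = delta_map(table1, table2)
    eta = normalize_deltas(deltas)
    if edges is None:
        edges = outlier_edges(deltas)
    z_scores = z_scores or {}
    out = []
    for e in edges:
        out.append(
            AnomalyRecord(
                edge=tuple(e),
                curv_control=table1.value(*e),
                curv_disease=table2.value(*e),
                delta=deltas.get(tuple(e), 0.0),
                norm_delta=eta.get(tuple(e), 0.0),
                weight_delta=weight_delta(net1, net2, e),
                z=z_scores.get(tuple(e)),
            )
        )
    return out
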