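"""End-to-end two-network curvature anomaly analysis.

Orchestrates: load control/disease matrices -> threshold-sparsify ->
per-edge curvature maps -> curvature differences and summary statistics ->
outlier selection -> [-1, 1] normalization and edge-weight baseline ->
null-model z-scores for the top outliers.  Produces three TSV reports:

``outliers.tsv``
    every outlier edge with its curvature difference,
``focal_edges.tsv``
    the z-scored top edges with both curvatures, Delta and z,
``comparison.tsv``
    normalized curvature difference vs the plain edge-weight difference
    for the focal edges.

All randomness flows from one seed recorded in the run log; reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .anomaly import build_records, delta_map, normalize_deltas, outlier_edges, summary_stats, weight_delta
from .forman import curvature_map
from .netio import load_matrix, sparsify, write_anomaly_table
from .significance import replicate_deltas

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    control_matrix: str
    disease_matrix: str
    labels: str | None = None
    outdir: str = "netcurv_out"
    threshold: float = 0.4
    d: int = 5
    mode: str = "chordal"
    cutoff: float | str = "auto"
    replicates: int = 100
    swap_factor: int = 5
    seed: int = 0
    top_k: int = 5
    extra_edges: list = field(default_factory=list)

    def __post_init__(self):
        if self.d not in (3, 4, 5):
            raise ValueError("order d must be 3, 4 or 5")
        if self.replicates < 2:
            raise ValueError("need at least 2 null replicates")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_curvature(matrix, labels=None, threshold=0.4, d=5, mode="chordal", out=None):
    """Single-network curvature table; returns the table, optionally writes TSV."""
    net = sparsify(load_matrix(matrix, labels), threshold)
    table = curvature_map(net, d, mode)
    if out is not None:
        with open(out, "w") as fh:
            fh.write("node_u\tnode_v\tcurvature\n")
            for (u, v), c in sorted(table.values.items()):
                fh.write(f"{u}\t{v}\t{c:.6f}\n")
    return table


def run_anomaly_pipeline(config: RunConfig) -> dict:
    """Run the full anomaly analysis; returns a result summary dict.

    Writes ``outliers.tsv``, ``focal_edges.tsv``, ``comparison.tsv`` and
    ``run_log.json`` into ``config.outdir``.  On any stage failure the
    partially written outputs are removed and the error re-raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, outdir: Path, written: list[Path]) -> dict:
    net1 = sparsify(load_matrix(config.control_matrix, config.labels), config.threshold)
    net2 = sparsify(load_matrix(config.disease_matrix, config.labels), config.threshold)
    logger.info("control: %d edges, disease: %d edges", net1.n_edges, net2.n_edges)

    t1 = curvature_map(net1, config.d, config.mode)
    t2 = curvature_map(net2, config.d, config.mode)
    deltas = delta_map(t1, t2)
    mean, std, hist = summary_stats(deltas)
    outliers = outlier_edges(deltas, config.cutoff)
    eta = normalize_deltas(deltas)

    focal = list(outliers[: config.top_k]) + [
        tuple(e) for e in config.extra_edges if tuple(e) not in outliers[: config.top_k]
    ]
    n_swaps1 = config.swap_factor * net1.n_edges
    n_swaps2 = config.swap_factor * net2.n_edges
    z_scores = {}
    for rank, e in enumerate(focal):
        res = replicate_deltas(
            net1,
            net2,
            e,
            d=config.d,
            mode=config.mode,
            R=config.replicates,
            n_swaps=max(n_swaps1, n_swaps2),
            seed=(config.seed * 100003 + rank) % (2**31),
        )
        z_scores[tuple(e)] = res.z

    out_outliers = outdir / "outliers.tsv"
    written.append(out_outliers)
    write_anomaly_table(
        build_records(net1, net2, t1, t2, edges=outliers, z_scores=z_scores), out_outliers
    )

    out_focal = outdir / "focal_edges.tsv"
    written.append(out_focal)
    with open(out_focal, "w") as fh:
        fh.write("edge_u\tedge_v\tcurv_control\tcurv_disease\tdelta\tz\n")
        for e in focal:
            z = z_scores.get(tuple(e))
            zs = "NA" if z is None else f"{z:.1f}"
            fh.write(
                f"{e[0]}\t{e[1]}\t{t1.value(*e):.6f}\t{t2.value(*e):.6f}"
                f"\t{deltas.get(tuple(e), 0.0):.6f}\t{zs}\n"
            )

    out_cmp = outdir / "comparison.tsv"
    written.append(out_cmp)
    with open(out_cmp, "w") as fh:
        fh.write("edge_u\tedge_v\tweight_delta\tnorm_delta\n")
        for e in focal:
            fh.write(
                f"{e[0]}\t{e[1]}\t{weight_delta(net1, net2, e):.6f}"
                f"\t{eta.get(tuple(e), 0.0):.6f}\n"
            )

    summary = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "n_edges_control": net1.n_edges,
        "n_edges_disease": net2.n_edges,
        "delta_mean": mean,
        "delta_std": std,
        "cutoff": 2.0 * std if config.cutoff == "auto" else float(config.cutoff),
        "n_outliers": len(outliers),
        "outliers": [list(e) for e in outliers],
        "z_scores": {f"{u},{v}": z for (u, v), z in z_scores.items()},
    }
    out_log = outdir / "run_log.json"
    written.append(out_log)
    with open(out_log, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
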