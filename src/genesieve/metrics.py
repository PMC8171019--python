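"""Partition-agreement and cluster-compactness statistics.

Both statistics are implemented directly from their printed definitions:

* Adjusted Rand index, computed from the contingency table between two
  labelings, chance-corrected so that random labelings score ~0 and a
  perfect match scores 1.

* Davies-Bouldin index over Euclidean geometry with mean centroids.  The
  default follows the printed form

      DBI = (1/k) * sum_i min_{j != i} (d_i + d_j) / d_ij,

  where d_i is the average distance of cluster i's samples to its centroid
  and d_ij the distance between centroids i and j.  The conventional
  definition replaces min with max; ``reduce="max"`` switches to it, and the
  discrepancy is logged once per process.  Smaller is better either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["MetricsResult", "contingency_table", "adjusted_rand_index",
           "davies_bouldin_index"]

_dbi_convention_logged = False


@dataclass
class MetricsResult:
    """ARI and DBI together with the intermediates that produced them."""

    ari: float | None = None
    dbi: float | None = None
    contingency: np.ndarray | None = None
    dbi_intra: np.ndarray | None = None  # d_i per cluster
    dbi_centroid_dist: np.ndarray | None = None  # d_ij matrix

    def to_dict(self) -> dict:
        out: dict = {}
        if self.ari is not None:
            out["ari"] = float(self.ari)
        if self.dbi is not None:
            out["dbi"] = float(self.dbi)
        return out


def _as_codes(labels) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes


def contingency_table(labels_true, labels_pred) -> np.ndarray:
    """Cross-tabulation t_ij of two labelings of the same samples."""
    a = _as_codes(labels_true)
    b = _as_codes(labels_pred)
    if a.size != b.size:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    table = np.zeros((a.max() + 1, b.max() + 1), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    return table


def adjusted_rand_index(labels_true, labels_pred) -> float:
    """Chance-corrected Rand index in [-1, 1]; 1 means a perfect match.

    Computed from the contingency table via pair counts.  When both
    labelings are degenerate (the chance-expected index equals its maximum,
    e.g. both single-cluster), the labelings agree exactly and 1 is returned.
    """
    t = contingency_table(labels_true, labels_pred)
    m = int(t.sum())
    if m < 2:
        raise ValueError("need at least 2 samples")

    def comb2(v):
        v = np.asarray(v, dtype=float)
        return v * (v - 1) / 2.0

    index = comb2(t).sum()
    sum_a = comb2(t.sum(axis=1)).sum()
    sum_b = comb2(t.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(m)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))


def davies_bouldin_index(
    x: ExpressionMatrix | np.ndarray,
    labels,
    reduce: str = "min",
    return_parts: bool = False,
):
    """Compactness/separation score; smaller means tighter, better-separated
    clusters.

    Parameters
    ----------
    x
        Sample coordinates, cells in rows.
    labels
        Cluster label per sample; at least 2 non-empty clusters.
    reduce
        ``"min"`` (default, the printed form) or ``"max"`` (the conventional
        Davies-Bouldin definition).
    """
    global _dbi_convention_logged
    if reduce not in ("min", "max"):
        raise ValueError("reduce must be 'min' or 'max'")
    if reduce == "min" and not _dbi_convention_logged:
        logger.info(
            "DBI uses the min-over-other-clusters form; pass reduce='max' "
            "for the conventional Davies-Bouldin definition"
        )
        _dbi_convention_logged = True
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    codes = _as_codes(labels)
    k = codes.max() + 1
    if k < 2:
        raise ValueError("need at least 2 clusters")
    centroids = np.stack([X[codes == c].mean(axis=0) for c in range(k)])
    intra = np.array(
        [np.linalg.norm(X[codes == c] - centroids[c], axis=1).mean() for c in range(k)]
    )
    dist = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    ratio = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if dist[i, j] == 0:
                raise ValueError(f"clusters {i} and {j} have coincident centroids")
            ratio[i, j] = (intra[i] + intra[j]) / dist[i, j]
    off = ~np.eye(k, dtype=bool)
    per_cluster = np.array(
        [
            (ratio[i][off[i]].min() if reduce == "min" else ratio[i][off[i]].max())
            for i in range(k)
        ]
    )
    dbi = float(per_cluster.mean())
    if return_parts:
        return dbi, MetricsResult(dbi=dbi, dbi_intra=intra, dbi_centroid_dist=dist)
    return dbi
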