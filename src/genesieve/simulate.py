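"""Synthetic scRNA-seq-like count matrices with planted cluster structure.

The generator is a deliberately simple caricature of droplet scRNA-seq data:
cluster structure is carried by a small set of informative genes whose mean
expression differs between clusters, buried among noise genes that share one
mean everywhere; counts are negative-binomial (over-dispersed Poisson) and
dropout is an independent per-entry zeroing on top.  It emulates the
sparsity, dimensionality and noise of real data well enough to exercise
every pipeline stage with a known ground truth; it does not model batch
effects, library-size gradients or doublets.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .matrix import ExpressionMatrix, save_expression

__all__ = ["SyntheticParams", "SyntheticDataset", "generate_dataset", "write_dataset"]


@dataclass
class SyntheticParams:
    """Generator settings.

    Defaults describe the standard fixture: 5 clusters of 100 cells over
    2000 genes of which 50 are informative.  ``effect_size`` is the standard
    deviation of per-cluster log-mean shifts for informative genes (the
    default 2.0 gives ~e^2 ~ 7-fold expression differences, typical of
    cell-type markers); ``dispersion`` is the
    negative-binomial dispersion (variance = mu + dispersion * mu^2, 0 means
    Poisson); ``dropout_rate`` is the independent per-entry zeroing
    probability.  Base gene log-means are Normal(base_log_mean, base_log_sd),
    i.e. a few counts per cell for a typical gene.
    """

    n_clusters: int = 5
    cells_per_cluster: int = 100
    n_informative: int = 50
    n_noise: int = 1950
    effect_size: float = 2.0
    dropout_rate: float = 0.3
    dispersion: float = 0.3
    base_log_mean: float = 1.5
    base_log_sd: float = 0.5
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Generated matrix plus the planted truth."""

    matrix: ExpressionMatrix
    labels: np.ndarray
    informative_genes: set[str] = field(default_factory=set)
    params: SyntheticParams | None = None


def generate_dataset(params: SyntheticParams | None = None, **kwargs) -> SyntheticDataset:
    """Draw a dataset; fully reproducible from ``params.seed``.

    Keyword arguments override fields of ``params`` for convenience.
    """
    p = params or SyntheticParams()
    if kwargs:
        p = SyntheticParams(**{**asdict(p), **kwargs})
    if p.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if p.n_informative < 0:
        raise ValueError("n_informative must be non-negative")
    if p.n_informative > 0 and p.effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if not 0 <= p.dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    if p.dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if p.cells_per_cluster < 2:
        raise ValueError("need at least 2 cells per cluster")

    rng = np.random.default_rng(p.seed)
    K = p.n_clusters
    m = K * p.cells_per_cluster
    n = p.n_informative + p.n_noise
    if n < 2:
        raise ValueError("need at least 2 genes in total")

    base = rng.normal(p.base_log_mean, p.base_log_sd, size=n)
    log_mu = np.tile(base, (K, 1))  # (K, n) per-cluster log-means
    informative_idx = np.arange(p.n_informative)
    log_mu[:, informative_idx] += rng.normal(
        0.0, p.effect_size, size=(K, p.n_informative)
    )
    mu = np.exp(log_mu)

    labels = np.repeat(np.arange(K), p.cells_per_cluster)
    cell_mu = mu[labels]  # (m, n)
    if p.dispersion == 0:
        counts = rng.poisson(cell_mu).astype(float)
    else:
        r = 1.0 / p.dispersion
        prob = r / (r + cell_mu)
        counts = rng.negative_binomial(r, prob).astype(float)
    if p.dropout_rate > 0:
        counts[rng.random(size=counts.shape) < p.dropout_rate] = 0.0

    # scatter informative genes through the matrix so position carries no signal
    width = len(str(n - 1))
    gene_ids = [f"g{j:0{width}d}" for j in range(n)]
    perm = rng.permutation(n)
    counts = counts[:, perm]
    gene_ids = [gene_ids[j] for j in perm]
    informative = {f"g{j:0{width}d}" for j in informative_idx}

    cw = len(str(m - 1))
    matrix = ExpressionMatrix(
        values=counts,
        cell_ids=[f"cell{i:0{cw}d}" for i in range(m)],
        gene_ids=gene_ids,
        unit_label="synthetic counts",
    )
    return SyntheticDataset(
        matrix=matrix, labels=labels, informative_genes=informative, params=p
    )


def write_dataset(ds: SyntheticDataset, outdir: str, format: str = "delimited") -> None:
    """Write matrix + labels TSV + a JSON manifest of the planted truth."""
    os.makedirs(outdir, exist_ok=True)
    if format == "mtx-triplet":
        save_expression(
            ds.matrix, os.path.join(outdir, "matrix.mtx"),
            layout="genes-by-cells", format="mtx-triplet",
        )
    else:
        save_expression(ds.matrix, os.path.join(outdir, "matrix.tsv"))
    with open(os.path.join(outdir, "labels.tsv"), "w") as fh:
        for cell, lab in zip(ds.matrix.cell_ids, ds.labels):
            fh.write(f"{cell}\t{int(lab)}\n")
    manifest = {
        "informative_genes": sorted(ds.informative_genes),
        "params": asdict(ds.params) if ds.params else None,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
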