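"""Preprocessing filters applied before weighting: rare-gene removal and
redundancy removal.

Two filters only, applied in this order:

1. drop genes expressed (value strictly > 0) in fewer than ``ceil(f * m)``
   cells, default f = 2% — genes at exactly the threshold are kept;
2. collapse groups of near-duplicate genes: a gene is absorbed by the first
   earlier-indexed retained gene whose Pearson correlation with it exceeds
   the threshold (default 0.99).  Constant genes have undefined correlation
   and are always retained.

No normalisation or log transform is applied by default; ``log_transform``
is offered as an explicit opt-in convenience.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PreprocessError
from .matrix import ExpressionMatrix

__all__ = [
    "PreprocessReport",
    "filter_rare_genes",
    "remove_redundant_genes",
    "preprocess",
    "log_transform",
]


@dataclass
class PreprocessReport:
    """Provenance of the preprocessing filters."""

    n_input_genes: int
    n_after_rare_filter: int
    n_after_redundancy: int
    removed_rare: list[str] = field(default_factory=list)
    redundancy_groups: list[tuple[str, list[str]]] = field(default_factory=list)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "n_input_genes": self.n_input_genes,
            "n_after_rare_filter": self.n_after_rare_filter,
            "n_after_redundancy": self.n_after_redundancy,
            "removed_rare": self.removed_rare,
            "redundancy_groups": [
                {"representative": rep, "absorbed": absorbed}
                for rep, absorbed in self.redundancy_groups
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def filter_rare_genes(
    x: ExpressionMatrix, min_cell_frac: float = 0.02
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Remove genes expressed in fewer than ``ceil(min_cell_frac * m)`` cells.

    "Expressed" means an expression value strictly greater than zero.  Genes
    expressed in exactly the threshold number of cells are kept.
    """
    if not 0 <= min_cell_frac < 1:
        raise ValueError(f"min_cell_frac must be in [0, 1), got {min_cell_frac}")
    m = x.n_cells
    threshold = math.ceil(min_cell_frac * m)
    n_expressing = (x.values > 0).sum(axis=0)
    keep = n_expressing >= threshold
    if not keep.any():
        raise PreprocessError(
            "rare-gene filter removed every gene; lower min_cell_frac "
            f"(currently {min_cell_frac})"
        )
    removed = [g for g, k in zip(x.gene_ids, keep) if not k]
    filtered = x.subset_genes(keep) if removed else x
    report = PreprocessReport(
        n_input_genes=x.n_genes,
        n_after_rare_filter=int(keep.sum()),
        n_after_redundancy=int(keep.sum()),
        removed_rare=removed,
    )
    return filtered, report


def remove_redundant_genes(
    x: ExpressionMatrix, pcc_threshold: float = 0.99
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Collapse genes whose pairwise Pearson correlation exceeds the threshold.

    Greedy sweep in gene-index order: each gene is compared against already
    retained genes and absorbed by the first one correlated above
    ``pcc_threshold`` (strictly).  Constant genes (zero variance, correlation
    undefined) are retained and never participate in absorption.
    """
    if x.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if not 0 < pcc_threshold <= 1:
        raise ValueError(f"pcc_threshold must be in (0, 1], got {pcc_threshold}")
    v = x.values
    m = x.n_cells
    sd = v.std(axis=0)
    constant = sd == 0
    # standardised columns so that z_i . z_j = PCC(i, j)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (v - v.mean(axis=0)) / (sd * np.sqrt(m))
    z[:, constant] = 0.0

    retained: list[int] = []
    groups: dict[int, list[str]] = {}
    absorbed_by: dict[int, int] = {}
    for j in range(x.n_genes):
        if constant[j]:
            retained.append(j)
            continue
        rep = None
        if retained:
            candidates = [i for i in retained if not constant[i]]
            if candidates:
                corr = z[:, candidates].T @ z[:, j]
                hits = np.flatnonzero(corr > pcc_threshold)
                if hits.size:
                    rep = candidates[hits[0]]
        if rep is None:
            retained.append(j)
        else:
            absorbed_by[j] = rep
            groups.setdefault(rep, []).append(x.gene_ids[j])

    keep = np.zeros(x.n_genes, dtype=bool)
    keep[retained] = True
    filtered = x.subset_genes(keep) if absorbed_by else x
    report = PreprocessReport(
        n_input_genes=x.n_genes,
        n_after_rare_filter=x.n_genes,
        n_after_redundancy=len(retained),
        redundancy_groups=[
            (x.gene_ids[rep], members) for rep, members in sorted(groups.items())
        ],
    )
    return filtered, report


def preprocess(
    x: ExpressionMatrix,
    min_cell_frac: float = 0.02,
    pcc_threshold: float = 0.99,
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Apply both filters (rare-gene removal, then redundancy removal)."""
    filtered, rare_report = filter_rare_genes(x, min_cell_frac)
    reduced, red_report = remove_redundant_genes(filtered, pcc_threshold)
    return reduced, PreprocessReport(
        n_input_genes=x.n_genes,
        n_after_rare_filter=rare_report.n_after_rare_filter,
        n_after_redundancy=red_report.n_after_redundancy,
        removed_rare=rare_report.removed_rare,
        redundancy_groups=red_report.redundancy_groups,
    )


def log_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Opt-in log2(x + 1) transform; never applied implicitly."""
    return ExpressionMatrix(
        values=np.log2(x.values + 1.0),
        cell_ids=list(x.cell_ids),
        gene_ids=list(x.gene_ids),
        unit_label=f"log2({x.unit_label or 'x'}+1)",
    )
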