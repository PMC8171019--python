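"""Gene selection from a fitted cluster x gene weight matrix.

Two screens run in sequence on the weight matrix W (fitted once; never
re-fitted between stages):

Stage 1, weight-magnitude screen.  Each gene is scored by its maximum weight
over clusters.  While the gene count is at or above the target (default
10000), the score range is split into N equal-width bins, with N from the
empirical Sturges rule N = round(3.322 * log10(n) - 1), and the lowest-score
nonempty bin is removed; N is recomputed from the surviving count each round.
Genes in the same score interval are thus kept or dropped together rather
than cut at an arbitrary threshold.

Stage 2, weight-deviation screen.  A gene whose weight varies strongly
across clusters behaves like a marker.  Variation is measured by the
coefficient of variation CV of the gene's K weights; because CV trends with
the mean weight, a line log(CV^2) = a * log10(mean) + b is fitted by
ordinary least squares and each gene's residual above the trend is z-scored.
Upper-tail normal p-values are attached and genes with p <= 0.05 survive.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clustering import WeightedClusterModel, fit
from .errors import SelectionError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningReport",
    "sturges_group_count",
    "weight_based_screen",
    "fit_cv_mean_trend",
    "deviation_based_screen",
    "select_genes",
]


@dataclass
class ScreeningReport:
    """Full provenance of the two screening stages."""

    survivors_s1: list[str]
    survivors_s2: list[str]
    group_history: list[dict] = field(default_factory=list)
    trend_fit: tuple[float, float] | None = None  # (slope a, intercept b)
    residuals: np.ndarray | None = None  # NaN where CV undefined
    z_scores: np.ndarray | None = None
    p_values: np.ndarray | None = None
    p_threshold: float = 0.05

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "n_survivors_s1": len(self.survivors_s1),
            "n_survivors_s2": len(self.survivors_s2),
            "survivors_s1": self.survivors_s1,
            "survivors_s2": self.survivors_s2,
            "group_history": self.group_history,
            "trend_fit": (
                {"slope": self.trend_fit[0], "intercept": self.trend_fit[1]}
                if self.trend_fit
                else None
            ),
            "p_threshold": self.p_threshold,
        }
        if self.p_values is not None:
            payload["p_values"] = [
                None if not np.isfinite(p) else float(p) for p in self.p_values
            ]
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def sturges_group_count(n_features: int) -> int:
    """Empirical Sturges bin count N = round(3.322 * log10(n) - 1), at least 2.

    Rounding is half-away-from-zero.
    """
    if n_features < 2:
        raise ValueError(f"need at least 2 features, got {n_features}")
    raw = 3.322 * math.log10(n_features) - 1.0
    rounded = int(math.floor(raw + 0.5))  # raw > -0.5 always holds here
    return max(rounded, 2)


def weight_based_screen(
    W: np.ndarray,
    gene_ids: list[str],
    target: int = 10000,
) -> tuple[np.ndarray, list[dict]]:
    """Iteratively drop the lowest bin of max-weight scores until fewer than
    ``target`` genes remain.

    Returns a boolean survivor mask over the input genes and the per-round
    group history (bin count, bin edges over the score range, removed count).
    The last nonempty bin is never removed if that would empty the gene set;
    all-equal scores form a single bin and stop the loop with everything
    retained.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[1]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length does not match W columns")
    scores = W.max(axis=0)
    alive = np.ones(n, dtype=bool)
    history: list[dict] = []
    while int(alive.sum()) >= target:
        n_current = int(alive.sum())
        s = scores[alive]
        lo, hi = float(s.min()), float(s.max())
        if lo == hi:
            logger.warning(
                "weight screen: all %d max-weights equal; stopping with all retained",
                n_current,
            )
            history.append(
                {"n_genes": n_current, "n_bins": 1, "edges": [lo, hi], "n_removed": 0}
            )
            break
        n_bins = sturges_group_count(n_current)
        edges = np.linspace(lo, hi, n_bins + 1)
        # bin index per gene; the top edge closes the last bin
        which = np.minimum(np.digitize(s, edges[1:-1], right=False), n_bins - 1)
        occupied = np.unique(which)
        lowest = int(occupied[0])
        drop_local = which == lowest
        if drop_local.all():
            logger.warning("weight screen: lowest bin holds every gene; stopping")
            history.append(
                {
                    "n_genes": n_current,
                    "n_bins": int(n_bins),
                    "edges": [float(e) for e in edges],
                    "n_removed": 0,
                }
            )
            break
        alive_idx = np.flatnonzero(alive)
        alive[alive_idx[drop_local]] = False
        history.append(
            {
                "n_genes": n_current,
                "n_bins": int(n_bins),
                "edges": [float(e) for e in edges],
                "n_removed": int(drop_local.sum()),
            }
        )
    return alive, history


def fit_cv_mean_trend(
    W: np.ndarray,
) -> tuple[tuple[float, float], np.ndarray, np.ndarray]:
    """Fit log(CV^2) = a * log10(mean) + b across genes by least squares.

    Per gene: mean and population standard deviation of its K weights;
    CV = sd / mean.  Genes with mean 0 or CV 0 are excluded from the fit and
    get NaN residuals (they receive p = 1 downstream).

    Returns ``((a, b), residuals, valid_mask)``; residuals are observed minus
    fitted log(CV^2), NaN outside ``valid_mask``.
    """
    W = np.asarray(W, dtype=float)
    K, n = W.shape
    if K < 2:
        raise ValueError("need at least 2 clusters to measure weight variation")
    mean = W.mean(axis=0)
    sd = W.std(axis=0)  # population sd, divisor K
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    # CVs at double-precision rounding noise are genuinely zero; keeping
    # them would inject log(CV^2) ~ -70 leverage points into the fit
    valid = np.isfinite(cv) & (cv > 1e-12)
    if int(valid.sum()) < 3:
        raise SelectionError(
            f"only {int(valid.sum())} genes with finite positive CV; cannot fit trend"
        )
    y = np.log(cv[valid] ** 2)
    x = np.log10(mean[valid])
    res = stats.linregress(x, y)
    a, b = float(res.slope), float(res.intercept)
    residuals = np.full(n, np.nan)
    residuals[valid] = y - (a * x + b)
    return (a, b), residuals, valid


def deviation_based_screen(
    residuals: np.ndarray,
    p_threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score the trend residuals and keep genes in the upper normal tail.

    ``z = (d - mean(d)) / sd(d)`` over genes with finite residuals;
    ``p = P(Z >= z)`` one-sided (a large positive residual means the gene's
    weights vary more across clusters than its mean predicts).  Genes with
    NaN residuals get z = NaN, p = 1.  Returns (survivor mask, z, p).
    """
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    valid = np.isfinite(residuals)
    z = np.full(n, np.nan)
    p = np.ones(n)
    if valid.any():
        d = residuals[valid]
        sd = d.std()
        if sd == 0:
            logger.warning("all residuals identical; no gene passes the deviation screen")
            z[valid] = 0.0
            p[valid] = 0.5
        else:
            z[valid] = (d - d.mean()) / sd
            p[valid] = stats.norm.sf(z[valid])
    survivors = p <= p_threshold
    return survivors, z, p


@dataclass
class SelectionConfig:
    """Tunable knobs of the end-to-end selection."""

    c_delta: float = 15.0
    max_iter: int = 100
    tol: float = 1e-6
    n_init: int = 5
    s1_target: int = 10000
    p_threshold: float = 0.05


def select_genes(
    x: ExpressionMatrix,
    n_clusters: int,
    config: SelectionConfig | None = None,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ScreeningReport, WeightedClusterModel]:
    """Full selection: fit the weight matrix once, then run both screens.

    The weight matrix is fitted on the full (preprocessed) gene set; the
    screens subset its columns without re-fitting.
    """
    cfg = config or SelectionConfig()
    model = fit(
        x,
        n_clusters,
        c_delta=cfg.c_delta,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        seed=seed,
        n_init=cfg.n_init,
    )
    mask_s1, history = weight_based_screen(model.W, x.gene_ids, target=cfg.s1_target)
    survivors_s1 = [g for g, keep in zip(x.gene_ids, mask_s1) if keep]
    W_s1 = model.W[:, mask_s1]
    trend, residuals, _valid = fit_cv_mean_trend(W_s1)
    mask_s2_local, z, p = deviation_based_screen(residuals, cfg.p_threshold)
    survivors_s2 = [g for g, keep in zip(survivors_s1, mask_s2_local) if keep]
    report = ScreeningReport(
        survivors_s1=survivors_s1,
        survivors_s2=survivors_s2,
        group_history=history,
        trend_fit=trend,
        residuals=residuals,
        z_scores=z,
        p_values=p,
        p_threshold=cfg.p_threshold,
    )
    logger.info(
        "gene selection: %d in, %d after weight screen (%.1f%%), %d after deviation screen (%.1f%%)",
        x.n_genes,
        len(survivors_s1),
        100 * len(survivors_s1) / x.n_genes,
        len(survivors_s2),
        100 * len(survivors_s2) / x.n_genes,
    )
    if not survivors_s2:
        raise SelectionError(
            "no gene passed the deviation screen; weights may be degenerate "
            "(see warnings) or p_threshold too strict"
        )
    reduced = x.subset_genes(survivors_s2)
    return reduced, report, model
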