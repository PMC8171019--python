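# Methods

## Model

`genesieve` clusters cells by weighted k-medians and uses the fitted
cluster × gene weight matrix as the evidence for gene selection. The
objective is

    J(K, W; χ) = Σ_k Σ_{i∈χ_k} Σ_j w_kj · d_ki^j + Σ_k δ_k Σ_j w_kj²,
    d_ki^j = |x_ij − c_kj|,   w_kj ∈ [0,1],   Σ_j w_kj = 1 per cluster,

a per-cluster feature-weighted Manhattan scatter plus a ridge penalty on
each weight row. The two terms pull in opposite directions: the scatter
term wants all weight on the features with the smallest within-cluster
spread, the ridge term wants uniform weights; δ_k sets the balance and is
itself re-estimated each sweep from the previous sweep's state,

    δ_k = C_δ · (Σ_{i∈χ_k} Σ_j w_kj d_ki^j) / Σ_j w_kj² ,

so the penalty tracks the scale of the data. Minimising J one block at a
time gives the sweep implemented in `clustering.fit`:

1. **assign** — each cell to the cluster minimising the weighted Manhattan
   distance D_ik = Σ_j w_kj|x_ij − c_kj| (ties: lowest index);
2. **centers** — per-feature median of each cluster's members (even-size
   clusters: midpoint of the middle pair); a coordinate whose weight is 0 is
   set to 0, which is inert because that weight also nullifies the
   coordinate's contribution to every distance;
3. **δ update** — the rule above, from the previous sweep's assignments,
   weights and centers; a degenerate cluster (zero scatter) keeps its δ;
4. **weight update** — the stationarity condition of the Lagrangian in
   closed form,

       w_kj = 1/n + (1/2δ_k) Σ_{i∈χ_k} [ (Σ_j' d_ki^j')/n − d_ki^j ].

   The bracketed terms cancel over j, so the raw row sums to exactly 1 (an
   invariant the tests assert at 1e-9). Raw entries may leave [0,1]; the
   row is projected by clamping negatives to 0 and renormalising.

Assumptions inherited from the model family: clusters are convex in the
weighted Manhattan geometry, the cluster count K is supplied by the caller
(no estimation), and distances are computed on the matrix as given — no
normalisation or log transform is applied implicitly (`log_transform` is an
explicit opt-in).

### Initialisation, restarts, convergence

Weights start uniform (1/n). Centers are K distinct cells drawn by
D²-weighted sampling (first center uniform, subsequent centers with
probability proportional to squared Manhattan distance to the nearest
chosen center) under the caller's seed. Plain uniform sampling is unusable
on skewed non-negative data: a low-count cell has small Manhattan distance
to everything, absorbs all cells and empties the other clusters. The first
δ comes from applying the δ rule to the initial state.

The sweep is restarted `n_init = 5` times from successive center draws of
the seeded generator and the run with the lowest final J is kept;
alternating minimisation of this objective has many local minima and the
final objective discriminates well between them. A sweep stops when the
assignment vector repeats, when the relative objective change drops below
`tol = 1e-6`, or after `max_iter = 100` sweeps. An empty cluster is
re-seeded at the cell farthest (weighted) from its own center and its
weight row resets to uniform. The full sweep with δ re-estimation is not
guaranteed monotone in J; only the assignment step and the median center
step are individually non-increasing, and only those two monotonicities are
asserted.

### C_δ

C_δ is the single most consequential free parameter. It controls how far
the weight rows move from uniform per sweep, and the dynamics have a sharp
failure mode at the low end: smaller δ concentrates weight on low-spread
(often near-constant) genes, which shrinks the weighted scatter, which
shrinks δ further — a feedback loop that collapses the row onto a handful
of uninformative genes and destroys the partition. At the high end the
weights pin to uniform and the model degenerates to plain k-medians.
Seed-averaged sweeps on the synthetic fixture (known ground truth) show a
broad stable plateau between the two regimes. Defaults are set per stage
from those sweeps: **15** for the selection pipeline (transcriptome-scale
matrices, where the stiffer prior also avoids zero-clamped weight entries
that distort the downstream CV screen) and **10** for a bare `fit`
(small pre-selected panels profit from a more adaptive prior). Both are
plateau values, not edges; both are surfaced in the CLI and logged.

## Gene selection

The weight matrix is fitted once on the full preprocessed gene set; the two
screens subset its columns and never re-fit.

**Weight screen** (`weight_based_screen`): gene score = max weight over
clusters. While the gene count is ≥ `s1_target` (default 10 000), the score
range is split into N equal-width bins with N from the empirical Sturges
rule `N = round(3.322·log10 n − 1)` (half-away-from-zero, floor 2), and the
lowest nonempty bin is removed. Equal-width (histogram) bins are the
reading consistent with a bin-count rule; genes in the same score interval
survive or fall together. Guards: all-equal scores form a single
bin and stop the loop; the last genes standing are never removed.

**Deviation screen** (`fit_cv_mean_trend` + `deviation_based_screen`): per
gene, the coefficient of variation of its K weights (population sd divided
by mean). Because mean and CV of weight columns are mechanically coupled
(rows sum to 1, so a gene that is down-weighted in one cluster both loses
mean and gains CV), CV is detrended: OLS of log(CV²) on log10(mean),
residual d_j per gene, z = (d − mean d)/sd d, one-sided upper-tail normal
p, survivors at p ≤ 0.05. Genes with zero mean weight or CV ≤ 1e-12 are
excluded from the fit and receive p = 1 — the tolerance matters because a
weight column that is constant up to double-precision rounding would
otherwise contribute log(CV²) ≈ −70 as a leverage point. No
multiple-testing correction is applied; the cut is a raw p threshold.

Known limitations of the screen, visible in its failure modes: a *single*
extreme marker among otherwise homogeneous genes is a high-leverage point
in the OLS and partially masks its own residual; genes with near-zero CV
produce a long left tail of residuals that inflates sd(d), making the
realised null selection rate conservative (≈3 % rather than the nominal
5 % on all-noise fixtures); and with K = 2 a marker whose two clusters are
equally tight receives symmetric weights and is invisible to a
variation-based screen. These are properties of the printed procedure, not
of the implementation.

## Preprocessing

Two filters, in order. (1) Rare-gene removal: a gene survives iff it is
expressed (value strictly > 0) in at least `ceil(min_cell_frac · m)` cells,
default 2 %; genes at exactly the threshold are kept. (2) Redundancy
removal: a greedy sweep in input gene order absorbs a gene into the first
earlier retained gene with Pearson correlation strictly above 0.99
(first-seen representative — deterministic and order-stable). Constant
genes have undefined correlation; they are retained and never absorb or get
absorbed. Correlation is computed on the values as loaded.

## Evaluation metrics

**Adjusted Rand index** from the contingency table, chance-corrected; the
degenerate case where the expected index equals its maximum (e.g. both
labelings single-cluster) returns 1. **Davies–Bouldin index** with
Euclidean distances and mean centroids; the default reduces per cluster
with `min` over the other clusters, with `reduce="max"` switching to the
conventional definition (the min form is kept as default for continuity
with the weighting literature this package follows; the discrepancy is
logged once per process). Smaller is better under either convention, but
the two are not interchangeable numerically. Coincident centroids raise an
error naming the cluster pair.

## Synthetic data generator

`simulate.generate_dataset` draws the study fixture: K clusters of equal
size; per-gene base log-means Normal(1.5, 0.5) (a few counts per cell for a
typical gene); informative genes additionally receive per-cluster log-mean
shifts Normal(0, effect_size) with effect_size = 2.0 by default (~e² ≈
7-fold expression differences — the scale of real cell-type markers, and
the regime in which reference clusterings of real benchmark data are
recoverable); noise genes share one mean across clusters. Counts are
negative-binomial with dispersion 0.3 (variance = μ + 0.3 μ²; 0 selects
Poisson), and dropout is an independent per-entry zeroing at rate 0.3.
Gene order is shuffled so column position carries no signal; everything is
reproducible from the seed. `n_informative = 0` produces the all-noise
fixture used for null calibration.

What the generator does *not* model: batch effects, library-size gradients,
doublets, gene–gene correlation beyond cluster structure, and
mean-dependent dropout. Passing tests on these fixtures therefore show
that the machinery recovers planted structure under idealised sparsity and
overdispersion — not that it will match any particular real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script use 500 cells × 2000 genes
(50 planted markers, 10 seeds) for recovery studies and 20 all-noise
fixtures for calibration; these sizes keep every planted quantity
measurable with tight seed-averaged noise while the whole study reruns in
about a minute. Tie-breaks are uniformly "lowest index wins". Assignments
are 0-based. Medians of even-sized clusters are midpoints. All screens and
fits are deterministic given the seed; the same seed reproduces bit-equal
weight matrices, gene lists and reports.
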