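# genesieve

Cluster-aware gene weighting and selection for single-cell RNA-seq
clustering.

scRNA-seq expression matrices are extremely sparse, high-dimensional and
noisy: of tens of thousands of genes, only a small subset separates the cell
types present in a sample, and the rest degrade every distance-based
clustering that touches them. Most gene-selection heuristics (expression
thresholds, highly-variable-gene screens) rank genes per cell and ignore the
clustering objective entirely. `genesieve` selects genes *from the
perspective of the clusters*: it fits a weighted k-medians model in which
every cluster carries its own gene-weight profile, then keeps the genes
whose weights are large or vary strongly across clusters — the behaviour of
marker genes.

## Method

Given a non-negative cells × genes matrix with `m` cells and `n` genes and a
cluster count `K`, the model minimises

```
J = Σ_k Σ_{i∈χ_k} Σ_j w_kj |x_ij − c_kj|  +  Σ_k δ_k Σ_j w_kj²
        s.t.  w_kj ∈ [0,1],  Σ_j w_kj = 1 for every k
```

where `χ_k` are hard cluster assignments, `c_k` the per-feature median
centers, `W` the K × n weight matrix and `δ_k` a per-cluster ridge strength
re-estimated each sweep (`δ_k = C_δ · weighted scatter / ‖w_k‖²`).
Alternating minimisation gives closed-form updates for each piece;
stationarity of the Lagrangian yields the weight row

```
w_kj = 1/n + (1 / 2δ_k) Σ_{i∈χ_k} [ (Σ_j' d_ki^j')/n − d_ki^j ],
```

so features whose within-cluster spread is below the cluster average gain
weight. Two screens then reduce the gene set:

1. **weight screen** — genes are binned by their maximum weight over
   clusters into N equal-width groups (N from the empirical Sturges rule
   `N = round(3.322·log10 n − 1)`) and the lowest group is dropped,
   iterating until fewer than 10 000 genes remain;
2. **deviation screen** — each gene's coefficient of variation of weights
   across clusters is detrended against its mean weight
   (`log CV² = a·log10 mean + b`, ordinary least squares), residuals are
   z-scored, and genes in the upper normal tail (`p ≤ 0.05`) survive.

Evaluation uses the adjusted Rand index (chance-corrected partition
agreement) and a Davies–Bouldin-style compactness score.

## Worked example

Simulate a dataset with 3 planted cell populations (30 marker genes among
500), run the full pipeline, and evaluate against the planted labels:

```bash
genesieve simulate --out demo --n-clusters 3 --cells-per-cluster 50 \
    --n-informative 30 --n-noise 470 --seed 1
genesieve run demo/matrix.tsv --out demo_out -k 3 \
    --labels demo/labels.tsv --seed 1
```

which prints

```
#Genes 500 | #Genes-S1 500 (100.00%) | #Genes-S2 26 (5.20%)
{
  "n_genes_input": 500,
  "n_genes_s1": 500,
  "n_genes_s2": 26,
  "n_iter": 5,
  "converged": true,
  "metrics": {
    "ari_weighted_clustering": 0.97993200471804,
    ...
  }
}
```

The weight screen is inactive here (500 < 10 000 genes); the deviation
screen keeps 26 genes (5.2 %), of which 26/30 planted markers are recovered
(87 % recall), and the weighted clustering agrees with the planted labels at
ARI 0.98. `demo_out/` holds the selected gene list, the reduced matrix, the
W/centers/δ bundle, assignments and all JSON reports. Subcommands
`preprocess`, `weight`, `select` and `evaluate` expose the individual
stages; inputs may be TSV/CSV (either orientation) or a 10x-style MTX
triplet.

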