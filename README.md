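# dfcselect

**Discriminative feature of cells (DFC)**: select a small, discriminative
subset of genes that separates one cell population from all other cells in
single-cell expression data, and classify the selected genes by their
per-cluster expression patterns.

## The problem

Marker genes for a cell population are conventionally called by per-gene
differential-expression tests (DEGs). With the sample sizes of scRNA-seq,
per-gene P-values shrink with √n and the DEG list balloons into thousands
of genes — far more than can be validated or interpreted. `dfcselect`
takes the discriminative view instead: each cell is a point in gene
expression space, and the genes worth reporting are the few whose joint
expression draws the decision boundary between the population of interest
(POI) and everything else. Because the boundary uses genes *jointly*, the
method can prefer gene pairs with correlated or mutually exclusive
expression that per-gene tests cannot distinguish from their neighbours.

## The model

For cells with expression vectors x_i and POI indicator y_i ∈ {0,1}, the
package fits an L1-penalized logistic regression with the **adaptive
LASSO** penalty in two steps:

1. **Ridge step** — an L2-penalized logistic fit (penalty chosen by
   cross-validated binomial deviance) produces reference coefficients
   β_ridge.
2. **Weighted LASSO step** — minimize

   (1/n) Σᵢ [log(1 + exp(ηᵢ)) − yᵢ ηᵢ] + λ Σⱼ wⱼ |βⱼ|,  η = β₀ + xᵀβ,

   with penalty factors wⱼ = 1/|β_ridge,ⱼ|^γ (γ = 1 by default; wⱼ = ∞
   excludes a feature). λ is chosen by stratified 10-fold cross-validation
   of binomial deviance.

Genes with nonzero weight at the selected λ are the DFC. The solver is an
in-house majorize–minimize coordinate-descent path algorithm with warm
starts; the penalized objective is provably non-increasing at every sweep.

Selected genes are then labeled **Strong** (expressed in ≥25% of cells in
1–2 clusters), **Weak** (≥3 clusters), or **Niche** (in no cluster),
separating classical markers from combinatorial and minor-subpopulation
features.

## Worked example

```python
import dfcselect as d

# four DE-equivalent genes; only (X3, X4) are correlated within groups
ds = d.generate_case1(seed=1)                       # 2000 cells x 4 genes
res = d.extract_dfc(ds.matrix, ds.annotation(), poi="A",
                    fraction=1.0, seed=1)
print(list(res.entry_order))    # ['X3', 'X4', 'X2', 'X1']
print(sorted(res.genes))        # ['X1', 'X2', 'X3', 'X4']
acc4 = d.classification_accuracy(ds.matrix, ds.y)
acc2 = d.classification_accuracy(ds.matrix, ds.y, features=["X3", "X4"])
print(round(acc4, 3), round(acc2, 3))   # 1.0 0.997
```

All four genes have identical per-gene statistics (same variance, same
mean gap — the same two-sample t-test P-value), yet the correlated pair
X3–X4 enters the solution path first and survives longest: discrimination
with just those two genes is nearly as accurate (0.997 on this draw) as
with all four (1.0; 0.999 and 0.995 on average over replicates). A
per-gene DEG test cannot make this distinction.

The same workflow runs from the shell:

```bash
dfc simulate case1 --n 1000 --seed 7 --out data/
dfc fit --matrix data/matrix.tsv --dense --clusters clusters.tsv \
        --poi A --fraction 1.0 --seed 1 --out result/
dfc classify --matrix data/matrix.tsv --dense --clusters clusters.tsv \
        --genes result/dfc_genes.tsv --out classes.tsv
```

`result/` contains `dfc_genes.tsv` (gene, signed weight, entry rank),
`fit.json` (λ grid, penalty factors, CV deviance, selected λ) and
`path.tsv` (the full coefficient path).

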