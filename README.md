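# bicca

Bi-order canonical correlation analysis for integrating two single-cell
data matrices that share **neither cells nor features** — e.g. scRNA-seq
with scATAC-seq, RNA with surface-protein panels (CITE-seq/CyTOF).

## The problem and the model

Let **X** ∈ ℝ^{M×K} and **Y** ∈ ℝ^{N×L} be two feature-by-cell matrices
from different modalities.  Because the features differ, they cannot be
correlated directly; a **modality fusion matrix** **Z** ∈ ℝ^{M×L}
bridges them by expressing Y's cells in X's feature space.  For
RNA+ATAC, Z is initialized (Z⁰) as a gene-activity matrix — peak counts
summed over gene bodies; for RNA+protein, Z⁰ is the expression of the
protein-coding genes.  Bi-order CCA then finds cell-level projections
**U** ∈ ℝ^{K×E}, **S** ∈ ℝ^{L×E} and feature-level projections
**T** ∈ ℝ^{M×E}, **V** ∈ ℝ^{N×E} maximizing

    (1−α) · tr{ (1−λ)/n_l (XU)ᵀZS + λ/n_r (ZᵀT)ᵀYᵀV } − α‖Z − Z⁰‖²_F

subject to UᵀU = SᵀS = TᵀT = VᵀV = I and ‖Z‖_F = 1, by alternating

1. (U, S) ← first E singular-vector pairs of XᵀZ,
2. (T, V) ← first E singular-vector pairs of ZYᵀ,
3. Z ← (1−α){(1−λ)/n_l · XUSᵀ + λ/n_r · TVᵀY} + αZ⁰, renormalized.

α ∈ [0, 1) sets how strongly Z stays anchored to its initializer;
λ ∈ [0, 1] balances the cell-level against the feature-level objective;
n_l, n_r are fixed scale factors from the iteration-0 CCVs.  Iteration
0 coincides with classical (diagonal-covariance) CCA of (X, Z⁰).  The
converged U and S place cells of both modalities in one E-dimensional
co-embedding, and the final Z is an in-silico multi-omics profile:
X-modality measurements imputed for Y's cells.

Downstream, the package L2-normalizes the co-embedding, builds a
shared-nearest-neighbor graph, clusters jointly with Leiden, transfers
cell-type labels across modalities with a calibrated SVM, scores the
integration (silhouette, modality-mixing entropy, anchoring distance,
transfer accuracy, imputation correlation), and links features across
modalities by correlating rows of Z with rows of Y.

## Worked example

```python
import bicca

# paired synthetic data: 4 cell types, 300 cells per modality,
# 500 x 800 features, 6 shared latent factors, half-corrupted Z0
X, Y, Z0, truth = bicca.simulate_paired(seed=1)
res = bicca.run_bicca(X, Y, Z0, E=6, alpha=0.1, lambda_=0.5, seed=1)
print(res.converged, res.iterations)            # True 2

coords, ids, tags = bicca.joint_coordinates(res)
from bicca.synth import annotation_for, pairing_indices
lt = bicca.transfer_labels(coords[:300], annotation_for(truth, X),
                           coords[300:], target_cell_ids=Y.cell_ids)
pred = bicca.CellAnnotation(lt.target_cell_ids, lt.predicted_labels)
per_type, macro, micro = bicca.label_transfer_accuracy(
    annotation_for(truth, Y), pred)
print(round(macro, 3))                          # 0.977

pairs = pairing_indices(truth, X, Y)
print(round(bicca.anchoring_distance_mean(coords[:300], coords[300:],
                                          pairs), 3))   # 0.4
```

`macro = 0.977` means 97.7 % of the held-out modality's cells receive
the correct type purely from the other modality's labels; the mean
anchoring distance 0.40 (0 = each cell coincides with its true partner,
2 = partner is the farthest cell) drops below the classical-CCA
iteration-0 baseline of 0.405, showing the fusion-matrix iterations
tightened the alignment.

The same pipeline is available from the shell:

```bash
bicca simulate --out sim/ --seed 1
bicca integrate --x sim/X.tsv --y sim/Y.tsv --z0 sim/Z0.tsv \
      --dims 6 --alpha 0.1 --lambda 0.5 --seed 1 --out run/
bicca metrics --result run/ --labels-x sim/labels_x.tsv \
      --labels-y sim/labels_y.tsv --pairing sim/pairing.tsv --out metrics.json
bicca network --result run/ --y sim/Y.tsv --cutoff 0.55 --out links.tsv
```

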