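# Methods

## Model

Two feature-by-cell matrices, X (M×K) and Y (N×L), are integrated
through a modality fusion matrix Z (M×L) that expresses Y's cells in
X's feature space.  The solver maximizes

    (1−α) tr{ (1−λ)/n_l (XU)ᵀZS + λ/n_r (ZᵀT)ᵀYᵀV } − α‖Z−Z⁰‖²_F

over orthonormal U (K×E), S (L×E), T (M×E), V (N×E) and unit-Frobenius
Z, by block-coordinate ascent: the cell-level pair (U, S) is the first
E singular-vector pairs of XᵀZ, the feature-level pair (T, V) of ZYᵀ,
and the fusion update adds αZ⁰ to the two rank-E reconstructions and
projects back to the unit sphere.  The CCA used throughout is the
diagonal-covariance variant — singular vectors of the plain
cross-product of row-standardized matrices, with no within-set
whitening — which is what makes the SVD identification exact.

Assumptions worth stating explicitly: features of the two modalities
are (noisily) linearly related through a shared low-dimensional cell
state; Z⁰ is informative about the true cross-modality map but need
not be accurate; cells need not be paired and cell counts may differ.

### Standardization

Feature rows of X and Y are z-scored (variance floor 1e−8;
(near-)constant rows are dropped with a warning; all-zero cell columns
are rejected).  Z⁰'s rows are z-scored the same way (constant rows
centered only) before the Frobenius normalization.  This last step is
a deliberate design choice: Z shares X's feature space, and leaving
Z⁰ un-row-scaled while X is row-scaled breaks the symmetry of the
(X, Z⁰) cross-product — on noiseless self-consistent data the U and S
clouds then sit visibly apart (mean anchoring distance ≈ 0.5 instead
of ≈ 0), an artifact of scale, not of biology.

### The objective that is monitored

The printed penalty weight (α on ‖Z−Z⁰‖²) and the printed update
(+αZ⁰) correspond to each other only up to a factor 2: on the unit
sphere, −(α/2)‖Z−Z⁰‖² differs from α·tr(Z⁰ᵀZ) by a constant, so the
update "add αZ⁰, renormalize" is the *exact* maximizer of the
objective whose quadratic penalty carries weight α/2.  Both the update
and the α-weighted objective evaluator are implemented exactly as
written above; the `objective_trace` and the convergence test monitor
the α/2-penalized potential, because that is the function the
alternation provably ascends (each of the three blocks solves its
subproblem exactly, so the trace is non-decreasing to machine
precision).  The two coincide at α = 0.  Convergence is declared when
the relative change of the monitored value falls below `tol`
(default 1e−4, `max_iter` 50); on the synthetic benchmark the solver
converges in 2–5 iterations.

### Scale factors

n_l = ‖XU⁰S⁰ᵀ‖²_F and n_r = ‖T⁰V⁰ᵀY‖²_F, computed once from the
iteration-0 CCVs of (X, Z⁰) and (Z⁰, Y).  With the squared norms the
two trace terms are balanced against *each other* (the role of λ), but
the reconstruction terms enter the fusion update with norm
(1−α)(1−λ)/‖XUSᵀ‖_F — small at realistic scales — so the normalized Z
remains dominated by the αZ⁰ anchor and the per-update improvements of
Z are incremental.  The converged Z still strictly improves anchoring
distance and imputation correlation over Z⁰ on every benchmark seed,
with correspondingly small margins.

### Fast (low-dimension) path

`mode="lowdim"` replaces X, Y, Z⁰ by low-dimension profiles: P_X and
P_z0 are the singular-value-scaled cell coordinates of the initial
(X, Z⁰) CCA (d components), P_Y the SVD scores of the standardized Y
(d′ components); the identical alternation then runs on
(P_X, P_Y, P_z0).  Cell co-embeddings agree with the full path up to
rotation (Procrustes disparity ≈ 1e−3 at d ≥ the true latent rank,
asserted ≤ 0.05 in tests).  Cross-products are accumulated over
feature blocks (`block_size`, default 1000) so peak memory does not
scale with the raw feature count; blocked and unblocked runs agree to
1e−6.

Full-feature imputation: in full mode the imputed profile *is* the
final Z.  In lowdim mode P_z is back-projected through the
least-squares feature loadings of the initial (X, Z⁰) CCA
(`impute_mode="reconstruct"`, default) or rebuilt from the X side only
(`"cell-blend"`).  The back-projection filters the part of a corrupted
Z⁰ that falls outside the CCA span: on noiseless data the median
per-cell Pearson correlation with the true profiles is ≥ 0.99, whereas
the full-mode Z retains its α-weighted share of the corrupted anchor
(per-cell median ≈ 0.86 under a half-corrupted Z⁰) — a direct
consequence of the squared-norm scale factors, not an implementation
artifact.

## Parameters

| parameter | default | meaning |
|---|---|---|
| E | min(30, rank−1) | latent dimensionality; start at the PCs used for single-modality clustering |
| α | 0.1 | anchor weight of Z⁰, 0 ≤ α < 1 (α→1 pins Z to Z⁰) |
| λ | 0.5 | balance of cell-level vs feature-level objective, 0…1 |
| tol | 1e−4 | relative objective change declaring convergence |
| max_iter | 50 | iteration cap |
| block_size | 1000 | feature-block length for cross-products |
| k | 20 | neighbors for SNN graph, mixing entropy, kNN vote |
| resolution | 0.5 | Leiden resolution for joint clustering |
| upstream_bp | 2000 | strand-aware 5′ extension for gene activity (0 = gene bodies only) |
| cutoff / top_n | 0.55 / 5 | feature-link retention (protein–gene convention) |

`parameter_grid_search` scans α ∈ {0, 0.1, …, 0.9} × λ ∈ {0, 0.1, …, 1}
(α = 1 is outside the domain, so the α grid stops at 0.9) and records
the two label-free metrics; `recommend()` returns the Pareto set over
(silhouette, mixing).

## Downstream conventions

* **L2 normalization**: each cell's co-embedding row is scaled to unit
  norm before any distance computation.
* **SNN graph**: neighbor sets are self-inclusive (the cell plus its
  k−1 nearest others, the common convention, so identical
  neighborhoods give weight exactly 1); edge weight = |shared|/k;
  zero-weight edges are pruned; distance ties break by cell index.
* **Leiden**: RB-configuration modularity with a resolution parameter;
  labels renumbered by decreasing cluster size; deterministic per seed.
* **Label transfer**: default `max_margin` is an RBF SVM with pairwise
  Platt-calibrated probabilities (the kernel and regularization are
  this package's defaults, not a claim about any reference tool);
  `knn_vote` is a distance-weighted 20-NN vote with the same
  normalized-score contract.  `restrict_to` renormalizes scores over a
  stated candidate label set — appropriate when the target modality is
  known to lack some source types, since cells adjacent to a
  target-absent source cluster otherwise leak into its label (see
  Limitations).
* **Metrics**: silhouette uses the three-branch per-cell formula with
  Euclidean distance (singleton clusters score 0; seeded subsample of
  10k above 20k cells); mixing entropy is the base-2 entropy of the
  two modality proportions among each cell's 20 nearest neighbors
  (0·log 0 := 0); anchoring distance is 2d_i/max(D_i) per paired cell,
  in [0, 2], averaged over all paired cells; transfer accuracy is the
  macro mean of the row-normalized confusion diagonal (micro also
  reported); imputation correlation flattens both matrices (per-type
  variants restrict columns), with zero-variance inputs reported as
  missing, never 0.
* **Gene activity**: 0-based half-open intervals everywhere internally
  (BED native; GTF converted on load); a peak contributes its full
  count to every gene window it overlaps by ≥ 1 bp; strand-aware
  upstream extension; genes without peaks keep zero rows.
* **Feature links**: Pearson r between rows of Z and rows of Y over the
  matched cells, computed blockwise; retained at r ≥ cutoff (or
  |r| with `--absolute`), at most top_n per anchor feature, ties by
  partner ID.
* **Determinism**: SVDs are exact and sign-fixed (largest-magnitude
  element of each left vector made positive) below 400 on the smaller
  cross-product dimension, seeded randomized SVD above; all other
  randomness flows from the user seed.

## The synthetic benchmark

`simulate_paired` draws type centroids in an E_true-dimensional latent
space (unit-scale centroids, per-cell jitter SD 0.3), emits X and Y as
Gaussian linear read-outs of the same latent states (paired cells,
loadings scaled so signal entries have roughly unit variance), and
forms Z⁰ as a convex blend of the exact cross-modality map with a
random linear map of Y, weight = `corruption`.  A negative-binomial
mode (gamma–Poisson, dispersion 10, optional dropout) provides
count-shaped data for realism tests.  Defaults — 300 cells per
modality, 4 balanced types, 500×800 features, E_true = 6, noise SD
1.0, corruption 0.5 — are the benchmark configuration used by the
tests and by `scripts/acceptance.py`; sizes were chosen so the full
pipeline runs in seconds on one core while every effect being tested
(type recovery, anchoring improvement, imputation improvement,
imbalance robustness) is comfortably resolved.  What this generator
does **not** emulate: count overdispersion structure of real
scRNA-seq (except in `nb` mode), peak co-accessibility, batch effects,
nonlinear feature relations, or doublets — passing tests show the
solver recovers planted linear structure, not that it handles every
pathology of real data.

`apply_imbalance` perturbs Y only: `downsample_major` removes a
fraction of the named (default: largest) types; `drop_minor` removes
whole types.  The ground-truth pairing and profiles follow the
surviving cells.

## Known limitations

* Dropping a whole type from one modality leaves that type's cells in
  the other modality without counterparts; they collapse onto their
  nearest type in the co-embedding, and an unrestricted classifier
  then assigns their label to adjacent retained cells.  Within the
  retained label space accuracy is unaffected; the unrestricted
  open-set behavior is measured by the tests but is not a supported
  recovery claim.
* The solver densifies matrices once feature rows are standardized;
  for very wide Y (10⁵+ features) use `mode="lowdim"`.
* Two-modality only; no batch covariates; no GPU path.
* Exact kNN up to 50k cells; above that an approximate seeded search
  is used when available.
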