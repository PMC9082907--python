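"""Normalization, feature selection, dimension reduction, and the
initial fusion matrix.

The gene-activity builder sums scATAC peak counts over gene bodies
(optionally extended upstream, strand-aware) to produce the customary
gene-score initializer Z0 for RNA+ATAC integration.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import scipy.sparse as sp
from intervaltree import IntervalTree

from .types import FusionMatrix, GeneModel, ModalityMatrix, ValidationError


def normalize_counts(
    m: ModalityMatrix, scheme: str = "log_cpm", cofactor: float = 5.0
) -> ModalityMatrix:
    """Normalize a count matrix.

    ``log_cpm``: log(1 + 1e4 * count / column_sum) — the standard
    library-size normalization for scRNA-seq.
    ``arcsinh``: asinh(value / cofactor) — the mass-cytometry transform
    (cofactor 5 by default).
    ``unit``: each feature divided by its maximum across cells, so
    intensities range in [0, 1] (CyTOF marker scaling).
    """
    X = m.values
    if scheme in ("log_cpm", "arcsinh"):
        data = X.data if sp.issparse(X) else X
        if data.size and data.min() < 0:
            raise ValidationError(f"{scheme} requires non-negative values")
    if scheme == "log_cpm":
        colsum = np.asarray(X.sum(axis=0)).ravel()
        zero = np.flatnonzero(colsum == 0)
        if zero.size:
            raise ValidationError(
                f"zero column sum under log_cpm for cell(s) "
                f"{[m.cell_ids[i] for i in zero[:5]]}"
            )
        if sp.issparse(X):
            out = X.tocsc(copy=True).astype(float)
            out.data *= np.repeat(1e4 / colsum, np.diff(out.indptr))
            out.data = np.log1p(out.data)
            values: np.ndarray | sp.spmatrix = out.tocsr()
        else:
            values = np.log1p(1e4 * X / colsum)
    elif scheme == "arcsinh":
        if cofactor <= 0:
            raise ValidationError("arcsinh cofactor must be positive")
        if sp.issparse(X):
            out = X.copy().astype(float)
            out.data = np.arcsinh(out.data / cofactor)
            values = out
        else:
            values = np.arcsinh(X / cofactor)
    elif scheme == "unit":
        dense = m.dense()
        rowmax = np.abs(dense).max(axis=1)
        scale = np.where(rowmax > 0, rowmax, 1.0)
        values = dense / scale[:, None]
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    return ModalityMatrix(values, list(m.feature_ids), list(m.cell_ids), m.modality)


def select_variable_features(m: ModalityMatrix, n: int) -> ModalityMatrix:
    """Keep the ``n`` features with the highest variance/mean dispersion.

    Dispersion is computed on the values as given (normalize first for
    the usual log-space behaviour); zero-mean features get dispersion 0.
    Ties break toward earlier rows, and selected features keep their
    original order.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if n > m.n_features:
        raise ValidationError(f"n={n} exceeds feature count {m.n_features}")
    dense = m.dense()
    mean = dense.mean(axis=1)
    var = dense.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean != 0, var / np.abs(mean), 0.0)
    disp[var == 0] = 0.0
    # stable sort on -disp => ties keep original feature order
    top = np.sort(np.argsort(-disp, kind="stable")[:n])
    return m.subset_features(top)


def _tfidf(X: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """TF = count/column sum; IDF = log(1 + n_cells/row nnz)."""
    X = sp.csr_matrix(X, dtype=float)
    n_cells = X.shape[1]
    colsum = np.asarray(X.sum(axis=0)).ravel()
    colsum[colsum == 0] = 1.0
    tf = X.multiply(1.0 / colsum).tocsr()
    nnz = np.asarray((X != 0).sum(axis=1)).ravel()
    idf = np.zeros(X.shape[0])
    idf[nnz > 0] = np.log(1.0 + n_cells / nnz[nnz > 0])
    return sp.csr_matrix(tf.multiply(idf[:, None]))


def _deterministic_svd(A: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense SVD truncated to d with a sign convention (largest-|.|
    element of each left vector made positive)."""
    W, s, Vt = np.linalg.svd(A, full_matrices=False)
    W, s, Vt = W[:, :d], s[:d], Vt[:d, :]
    for j in range(W.shape[1]):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
            Vt[j, :] = -Vt[j, :]
    return W, s, Vt


def reduce_dimension(
    m: ModalityMatrix,
    d: int,
    scheme: str = "pca",
    drop_first: bool = False,
    rank_tol: float = 1e-10,
) -> np.ndarray:
    """Reduce a modality to ``d`` components; returns a (d x cells)
    score matrix ordered by decreasing singular value.

    ``pca``: feature-centered truncated SVD. ``lsi``: TF-IDF then
    truncated SVD, with ``drop_first`` discarding the depth-driven
    leading component (common for chromatin accessibility).
    If the matrix rank is below ``d`` only the rank components are
    returned, with a warning.
    """
    if d < 1 or d > min(m.shape):
        raise ValidationError(f"d={d} outside [1, min{m.shape}]")
    if scheme == "pca":
        A = m.dense()
        A = A - A.mean(axis=1, keepdims=True)
    elif scheme == "lsi":
        A = np.asarray(_tfidf(m.values).todense())
    else:
        raise ValueError(f"unknown reduction scheme {scheme!r}")
    n_want = d + 1 if (scheme == "lsi" and drop_first) else d
    W, s, Vt = _deterministic_svd(A, min(n_want, min(A.shape)))
    if scheme == "lsi" and drop_first and len(s) > 1:
        W, s, Vt = W[:, 1:], s[1:], Vt[1:, :]
    rank = int(np.sum(s > rank_tol * (s[0] if len(s) else 1.0)))
    if rank < len(s):
        warnings.warn(
            f"requested {len(s)} components but matrix rank is {rank}; returning {rank}",
            stacklevel=2,
        )
        W, s, Vt = W[:, :rank], s[:rank], Vt[:rank, :]
    return s[:, None] * Vt  # scores, (d x cells)


_PEAK_ID = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_peak_id(peak_id: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (0-based half-open)."""
    m = _PEAK_ID.match(peak_id.strip())
    if m is None:
        raise ValidationError(f"unparseable peak ID {peak_id!r} (expected chrom:start-end)")
    start, end = int(m["start"]), int(m["end"])
    if start >= end:
        raise ValidationError(f"peak {peak_id!r}: empty interval")
    return m["chrom"], start, end


def build_gene_activity(
    peaks: ModalityMatrix,
    genes: list[GeneModel],
    upstream_bp: int = 2000,
) -> FusionMatrix:
    """Sum peak counts over gene bodies to build a gene-activity Z0.

    A gene's window is its body extended ``upstream_bp`` on the 5'
    side (strand-aware).  A peak overlapping the window by >=1 bp
    contributes its full count; peaks spanning two genes count for
    both.  Genes with no overlapping peak keep an all-zero row.
    """
    if upstream_bp < 0:
        raise ValidationError("upstream_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for idx, pid in enumerate(peaks.feature_ids):
        chrom, start, end = parse_peak_id(pid)
        trees.setdefault(chrom, IntervalTree()).addi(start, end, idx)

    P = sp.csr_matrix(peaks.values, dtype=float)
    activity = np.zeros((len(genes), peaks.n_cells))
    missing_chroms = set()
    for gi, g in enumerate(genes):
        if g.strand == "+":
            w_start, w_end = max(0, g.start - upstream_bp), g.end
        else:
            w_start, w_end = g.start, g.end + upstream_bp
        tree = trees.get(g.chrom)
        if tree is None:
            missing_chroms.add(g.chrom)
            continue
        hits = sorted(iv.data for iv in tree.overlap(w_start, w_end))
        if hits:
            activity[gi] = np.asarray(P[hits, :].sum(axis=0)).ravel()
    if missing_chroms:
        warnings.warn(
            f"chromosomes without peaks: {sorted(missing_chroms)}", stacklevel=2
        )
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("duplicate gene IDs in gene models")
    return FusionMatrix(activity, gene_ids, list(peaks.cell_ids))


def standardize_fusion(z: FusionMatrix) -> FusionMatrix:
    """Scale Z to unit Frobenius norm (idempotent, scale-invariant)."""
    norm = np.linalg.norm(z.values)
    if norm == 0:
        raise ValidationError("cannot standardize an all-zero fusion matrix")
    return FusionMatrix(z.values / norm, list(z.row_ids), list(z.col_ids))
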