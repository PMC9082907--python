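"""Feature-feature link inference.

After integration the fusion matrix Z (X-space profiles of Y's cells)
and Y itself describe the same cells, so correlating a row of Z with a
row of Y links features across modalities — e.g. a protein with the
genes that track its abundance, or a gene with nearby accessible
peaks.  Links are filtered at a correlation cutoff (0.55 for the
protein-gene case) and capped per anchor feature (top 5 by default).
"""

from __future__ import annotations

import logging

import numpy as np

from .types import FeatureLinkSet, FusionMatrix, ModalityMatrix, ValidationError

logger = logging.getLogger("bicca")


def _rowwise_correlation(
    A: np.ndarray, B: np.ndarray, block_size: int = 512
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All row-of-A x row-of-B Pearson correlations, blockwise over A.

    Returns (R, ok_a, ok_b): zero-variance rows are flagged and their
    correlations set to NaN.
    """
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(Ac, axis=1)
    sb = np.linalg.norm(Bc, axis=1)
    ok_a, ok_b = sa > 0, sb > 0
    R = np.full((A.shape[0], B.shape[0]), np.nan)
    Bn = np.where(ok_b[:, None], Bc / np.where(sb[:, None] == 0, 1, sb[:, None]), 0)
    for lo in range(0, A.shape[0], block_size):
        hi = lo + block_size
        blk = Ac[lo:hi] / np.where(sa[lo:hi, None] == 0, 1, sa[lo:hi, None])
        R[lo:hi] = blk @ Bn.T
    R[~ok_a, :] = np.nan
    R[:, ~ok_b] = np.nan
    return R, ok_a, ok_b


def infer_feature_links(
    Z: FusionMatrix,
    Y: ModalityMatrix,
    cutoff: float = 0.55,
    top_n: int = 5,
    anchor: str = "x_features",
    absolute: bool = False,
    block_size: int = 512,
) -> FeatureLinkSet:
    """Correlate fusion rows with second-modality rows over shared cells.

    Pearson r is computed for every (Z row, Y row) pair across the
    matched cell columns; pairs with r >= cutoff (|r| >= cutoff when
    ``absolute``) survive, and at most ``top_n`` partners are kept per
    anchor feature, ranked by r (ties broken by partner feature ID).
    """
    if list(Z.col_ids) != list(Y.cell_ids):
        try:
            order = [Z.col_ids.index(c) for c in Y.cell_ids]
        except ValueError as e:
            raise ValidationError("Z and Y must share their cell axis") from e
        Z = FusionMatrix(Z.values[:, order], list(Z.row_ids), list(Y.cell_ids))
    if anchor not in ("x_features", "y_features"):
        raise ValueError(f"unknown anchor {anchor!r}")
    R, ok_z, ok_y = _rowwise_correlation(Z.values, Y.dense(), block_size)
    n_skipped = int((~ok_z).sum() + (~ok_y).sum())
    if n_skipped:
        logger.info("skipped %d zero-variance feature rows", n_skipped)
    score = np.abs(R) if absolute else R
    with np.errstate(invalid="ignore"):
        zi, yi = np.nonzero(score >= cutoff)
    candidates = [
        (Z.row_ids[i], Y.feature_ids[j], float(R[i, j])) for i, j in zip(zi, yi)
    ]
    # group by anchor, keep top_n by score (ties -> partner ID order)
    grouped: dict[str, list[tuple[str, str, float]]] = {}
    for fx, fy, r in candidates:
        key, partner = (fx, fy) if anchor == "x_features" else (fy, fx)
        grouped.setdefault(key, []).append((fx, fy, r))
    edges: list[tuple[str, str, float]] = []
    for key in sorted(grouped):
        partner_col = 1 if anchor == "x_features" else 0
        ranked = sorted(
            grouped[key], key=lambda e: (-(abs(e[2]) if absolute else e[2]), e[partner_col])
        )
        edges.extend(ranked[:top_n])
    return FeatureLinkSet(
        edges=edges,
        cutoff=cutoff,
        top_n=top_n,
        anchor=anchor,
        n_skipped_zero_variance=n_skipped,
    )


def save_links(links: FeatureLinkSet, path) -> None:
    """Write edges as a 3-column TSV (feature_x, feature_y, r)."""
    with open(path, "w") as fh:
        fh.write("feature_x\tfeature_y\tr\n")
        for fx, fy, r in links.edges:
            fh.write(f"{fx}\t{fy}\t{r:.6f}\n")
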