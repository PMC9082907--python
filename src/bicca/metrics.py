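"""Integration quality metrics and the alpha/lambda grid search.

Three label-aware and two label-free measures quantify how well two
modalities were integrated:

* silhouette — separation of cell types in the co-embedding;
* alignment mixing entropy — per-cell entropy of modality proportions
  among the 20 nearest neighbors (1 = perfectly mixed);
* anchoring distance — 2 d_i / max(D_i) between a cell and its true
  cross-modality partner (paired data only; 0 = perfect anchor);
* label-transfer accuracy — macro-averaged diagonal of the
  row-normalized confusion matrix;
* imputation correlation — Pearson r between the imputed fusion
  profiles and ground-truth measurements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding import knn_indices
from .types import CellAnnotation, FusionMatrix, ModalityMatrix, ValidationError

logger = logging.getLogger("bicca")

_SILHOUETTE_SUBSAMPLE_AT = 20_000
_SILHOUETTE_SUBSAMPLE_TO = 10_000


def silhouette_scores(coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-cell silhouette s(i) with Euclidean distance.

    s(i) = 1 - a(i)/b(i) if a(i) < b(i); 0 if equal; b(i)/a(i) - 1
    otherwise, where a(i) is the mean distance to i's own cluster and
    b(i) the mean distance to the nearest other cluster.  Cells in
    singleton clusters score 0.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    n = coords.shape[0]
    d = np.sqrt(
        np.maximum(
            np.sum(coords**2, axis=1)[:, None]
            + np.sum(coords**2, axis=1)[None, :]
            - 2 * coords @ coords.T,
            0.0,
        )
    )
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in classes}
    singleton = {c for c, m in members.items() if len(m) == 1}
    if singleton:
        warnings.warn(f"singleton clusters scored 0: {sorted(singleton)}", stacklevel=2)
    for i in range(n):
        c = labels[i]
        if c in singleton:
            continue
        own = members[c]
        a = d[i, own].sum() / (len(own) - 1)
        b = min(d[i, members[o]].mean() for o in classes if o != c)
        if a < b:
            s[i] = 1.0 - a / b
        elif a > b:
            s[i] = b / a - 1.0
    return s


def silhouette_mean(
    coords: np.ndarray,
    labels: CellAnnotation | np.ndarray,
    seed: int = 0,
) -> float:
    """Mean silhouette over cells; seeded subsample above 20k cells."""
    lab = np.asarray(labels.labels if isinstance(labels, CellAnnotation) else labels)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != len(lab):
        raise ValidationError("coordinates and labels disagree in length")
    if coords.shape[0] >= _SILHOUETTE_SUBSAMPLE_AT:
        rng = np.random.default_rng(seed)
        keep = rng.choice(coords.shape[0], _SILHOUETTE_SUBSAMPLE_TO, replace=False)
        logger.info("silhouette subsampled to %d cells", len(keep))
        coords, lab = coords[keep], lab[keep]
    return float(silhouette_scores(coords, lab).mean())


def mixing_entropy(p1: float) -> float:
    """Binary entropy H = -p1 log2 p1 - p2 log2 p2 with 0 log 0 := 0."""
    h = 0.0
    for p in (p1, 1.0 - p1):
        if p > 0:
            h -= p * np.log2(p)
    return h


def mixing_mean(
    coords: np.ndarray, modality_tags: list[str] | np.ndarray, k: int = 20
) -> float:
    """Mean per-cell modality-mixing entropy over k nearest neighbors."""
    tags = np.asarray(modality_tags)
    uniq = np.unique(tags)
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 modality tags, got {list(uniq)}")
    coords = np.asarray(coords, dtype=float)
    idx = knn_indices(coords, k)
    is_first = tags == uniq[0]
    hs = [mixing_entropy(float(is_first[row].mean())) for row in idx]
    return float(np.mean(hs))


def anchoring_distances(
    coords_x: np.ndarray,
    coords_y: np.ndarray,
    pairing: dict[int, int] | list[tuple[int, int]],
) -> np.ndarray:
    """Per-cell anchoring distance 2 d_i / max(D_i).

    D_i collects the Euclidean distances from paired cell i (in X) to
    every cell of the other modality; d_i is the distance to its true
    partner.  0 means perfectly anchored; 2 is the formula maximum.
    """
    pairs = list(pairing.items()) if isinstance(pairing, dict) else list(pairing)
    if not pairs:
        raise ValidationError("empty pairing")
    coords_x = np.asarray(coords_x, dtype=float)
    coords_y = np.asarray(coords_y, dtype=float)
    out = np.empty(len(pairs))
    for n, (i, j) in enumerate(pairs):
        D = np.linalg.norm(coords_y - coords_x[i], axis=1)
        out[n] = 2.0 * D[j] / D.max()
    return out


def anchoring_distance_mean(
    coords_x: np.ndarray,
    coords_y: np.ndarray,
    pairing: dict[int, int] | list[tuple[int, int]],
) -> float:
    return float(anchoring_distances(coords_x, coords_y, pairing).mean())


def confusion_matrix(truth: CellAnnotation, predicted: CellAnnotation) -> pd.DataFrame:
    """Counts C[i, j] of type-i cells predicted as type j.

    Rows cover the truth types, columns the union of truth and
    predicted types (a predicted type absent from the truth stays as an
    error column).
    """
    t = truth.as_dict()
    p = predicted.as_dict()
    if set(t) != set(p):
        raise ValidationError("truth and prediction must cover identical cell sets")
    truth_types = sorted(set(t.values()))
    all_types = sorted(set(t.values()) | set(p.values()))
    C = pd.DataFrame(0, index=truth_types, columns=all_types, dtype=int)
    for cell, tt in t.items():
        C.loc[tt, p[cell]] += 1
    return C


def label_transfer_accuracy(
    truth: CellAnnotation, predicted: CellAnnotation
) -> tuple[dict[str, float], float, float]:
    """Per-type, macro and micro label-transfer accuracy.

    The confusion matrix is row-normalized; per-type accuracy is its
    diagonal, the overall (macro) accuracy the mean across types, and
    the micro accuracy the plain fraction of correct cells.
    """
    C = confusion_matrix(truth, predicted)
    row_sums = C.sum(axis=1)
    per_type = {
        t: (float(C.loc[t, t]) / row_sums[t] if t in C.columns else 0.0)
        for t in C.index
    }
    macro = float(np.mean(list(per_type.values())))
    diag = sum(C.loc[t, t] for t in C.index if t in C.columns)
    micro = float(diag / C.values.sum())
    return per_type, macro, micro


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    a = a.ravel()
    b = b.ravel()
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def imputation_correlation(
    Z: FusionMatrix | np.ndarray,
    X_truth: ModalityMatrix | np.ndarray,
    labels: CellAnnotation | None = None,
) -> tuple[float | None, dict[str, float | None]]:
    """Pearson correlation of imputed and ground-truth profiles.

    ``Z`` and ``X_truth`` must share their shape (the imputed Z for Y's
    cells versus their actually measured X-modality profiles, available
    for co-assayed or simulated data).  The overall value flattens both
    matrices; per-type values restrict columns to each cell type.
    Zero-variance inputs yield ``None`` (undefined), not 0.
    """
    Zv = Z.values if isinstance(Z, FusionMatrix) else np.asarray(Z, dtype=float)
    Xv = X_truth.dense() if isinstance(X_truth, ModalityMatrix) else np.asarray(X_truth, dtype=float)
    if Zv.shape != Xv.shape:
        raise ValidationError(f"shape mismatch: Z {Zv.shape} vs truth {Xv.shape}")
    overall = _pearson(Zv, Xv)
    per_type: dict[str, float | None] = {}
    if labels is not None:
        lab = np.asarray(labels.labels)
        if len(lab) != Zv.shape[1]:
            raise ValidationError("labels must annotate Z's columns")
        for t in np.unique(lab):
            cols = lab == t
            per_type[str(t)] = _pearson(Zv[:, cols], Xv[:, cols])
    return overall, per_type


@dataclass
class GridSearchTable:
    """Result of the alpha/lambda grid search."""

    table: pd.DataFrame  # columns: alpha, lambda, silhouette_mean, mixing_mean
    grid_alpha: list[float] = field(default_factory=list)
    grid_lambda: list[float] = field(default_factory=list)

    def recommend(self) -> pd.DataFrame:
        """Pareto-optimal rows over (silhouette_mean, mixing_mean)."""
        df = self.table.dropna(subset=["silhouette_mean", "mixing_mean"])
        keep = []
        for i, row in df.iterrows():
            dominated = (
                (df["silhouette_mean"] >= row["silhouette_mean"])
                & (df["mixing_mean"] >= row["mixing_mean"])
                & (
                    (df["silhouette_mean"] > row["silhouette_mean"])
                    | (df["mixing_mean"] > row["mixing_mean"])
                )
            ).any()
            if not dominated:
                keep.append(i)
        return df.loc[keep]


DEFAULT_ALPHA_GRID = [round(0.1 * i, 1) for i in range(10)]  # 0..0.9; alpha < 1
DEFAULT_LAMBDA_GRID = [round(0.1 * i, 1) for i in range(11)]  # 0..1


def parameter_grid_search(
    X,
    Y,
    Z0,
    E: int,
    labels: CellAnnotation,
    grid_alpha: list[float] | None = None,
    grid_lambda: list[float] | None = None,
    snn_k: int = 20,
    **run_kwargs,
) -> GridSearchTable:
    """Run bi-CCA per (alpha, lambda) and score each co-embedding.

    ``labels`` annotates the concatenated cells (X's then Y's) with the
    types from single-modality clustering; the two label-free metrics
    of integration — silhouette (accuracy) and mixing entropy
    (alignment) — are recorded per grid point.  A failing run leaves a
    missing row rather than aborting the search.
    """
    from .core import run_bicca
    from .embedding import joint_coordinates

    grid_alpha = DEFAULT_ALPHA_GRID if grid_alpha is None else grid_alpha
    grid_lambda = DEFAULT_LAMBDA_GRID if grid_lambda is None else grid_lambda
    for a in grid_alpha:
        if not (0.0 <= a < 1.0):
            raise ValidationError(f"alpha grid value {a} outside [0, 1)")
    rows = []
    for a in sorted(grid_alpha):
        for lam in sorted(grid_lambda):
            try:
                res = run_bicca(X, Y, Z0, E=E, alpha=a, lambda_=lam, **run_kwargs)
                coords, ids, tags = joint_coordinates(res)
                ann = labels.reorder(ids)
                sil = silhouette_mean(coords, ann)
                mix = mixing_mean(coords, tags, k=min(snn_k, coords.shape[0] - 1))
            except Exception as e:  # noqa: BLE001 - record and continue
                logger.warning("grid point alpha=%s lambda=%s failed: %s", a, lam, e)
                sil = mix = np.nan
            rows.append(
                {"alpha": a, "lambda": lam, "silhouette_mean": sil, "mixing_mean": mix}
            )
    df = pd.DataFrame(rows).sort_values(["alpha", "lambda"]).reset_index(drop=True)
    return GridSearchTable(df, list(grid_alpha), list(grid_lambda))
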