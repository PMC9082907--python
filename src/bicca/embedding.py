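"""Post-integration processing in the shared latent space.

Cells from both modalities receive coordinates in the E-dimensional
co-embedding (rows of U and S).  L2 normalization removes global scale
differences; a shared-nearest-neighbor graph plus Leiden community
detection yields joint clusters; a classifier trained on one
modality's coordinates transfers cell-type labels to the other.
"""

from __future__ import annotations

import warnings

import igraph
import leidenalg
import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .types import (
    CellAnnotation,
    CoEmbedding,
    IntegrationResult,
    LabelTransferResult,
    NeighborGraph,
    ValidationError,
)

_EXACT_KNN_MAX = 50_000
_ARGSORT_KNN_MAX = 4_096


def l2_normalize_rows(coords: np.ndarray) -> np.ndarray:
    """Scale each cell's coordinate vector to unit Euclidean norm."""
    coords = np.asarray(coords, dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValidationError(f"zero-norm embedding row(s) at {zero[:5].tolist()}")
    return coords / norms[:, None]


def l2_normalize(emb: CoEmbedding) -> CoEmbedding:
    """L2-normalize the cell projections U and S of a co-embedding."""
    return CoEmbedding(
        U=l2_normalize_rows(emb.U),
        S=l2_normalize_rows(emb.S),
        T=emb.T,
        V=emb.V,
        canonical_correlations=emb.canonical_correlations,
        singular_values=emb.singular_values,
    )


def joint_coordinates(result: IntegrationResult) -> tuple[np.ndarray, list[str], list[str]]:
    """Stacked L2-normalized coordinates for all cells of both
    modalities, with cell IDs and modality tags."""
    emb = l2_normalize(result.embedding)
    coords = np.vstack([emb.U, emb.S])
    ids = list(result.cell_ids_x) + list(result.cell_ids_y)
    tags = ["x"] * emb.U.shape[0] + ["y"] * emb.S.shape[0]
    return coords, ids, tags


def knn_indices(coords: np.ndarray, k: int, seed: int | None = None) -> np.ndarray:
    """k nearest neighbors per point (self excluded), Euclidean.

    Exact for moderate sizes (distance ties broken by point index via a
    stable argsort below ~4k points); seeded approximate search above
    50k points when pynndescent is available.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be below the cell count {n}")
    if n <= _ARGSORT_KNN_MAX:
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
        np.fill_diagonal(d2, np.inf)
        order = np.argsort(d2, axis=1, kind="stable")
        return order[:, :k]
    if n <= _EXACT_KNN_MAX:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        out = np.empty((n, k), dtype=int)
        for i in range(n):
            row = idx[i][idx[i] != i][:k]
            out[i] = row
        return out
    try:
        from pynndescent import NNDescent
    except ImportError:  # pragma: no cover - exact fallback
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        return np.stack([idx[i][idx[i] != i][:k] for i in range(n)])
    index = NNDescent(coords, n_neighbors=k + 1, random_state=seed)
    idx, _ = index.neighbor_graph
    return np.stack([idx[i][idx[i] != i][:k] for i in range(n)])


def build_snn_graph(
    coords: np.ndarray,
    k: int = 20,
    node_ids: list[str] | None = None,
    modality_of: list[str] | None = None,
    prune: float = 0.0,
    seed: int | None = None,
) -> NeighborGraph:
    """Shared-nearest-neighbor graph in the L2-normalized space.

    Each cell's neighbor set contains itself plus its k-1 Euclidean
    nearest others (the usual self-inclusive convention, so two cells
    with identical neighborhoods get weight exactly 1); cells are
    linked to the members of their set, with edge weight the fraction
    of shared members between the two sets.  Edges with weight <=
    ``prune`` are dropped (default keeps any positive weight).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be below the cell count {n}")
    if k < 2:
        raise ValidationError("k must be >= 2")
    idx = knn_indices(coords, k - 1, seed=seed)
    neigh_sets = [set(row) | {i} for i, row in enumerate(idx)]
    weights: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in idx[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) not in weights:
                w = len(neigh_sets[a] & neigh_sets[b]) / k
                if w > prune:
                    weights[(a, b)] = w
    edges = [(a, b, w) for (a, b), w in sorted(weights.items())]
    nodes = node_ids if node_ids is not None else [f"cell{i}" for i in range(n)]
    tags = modality_of if modality_of is not None else ["?"] * n
    touched = {e[0] for e in edges} | {e[1] for e in edges}
    isolated = n - len(touched)
    if isolated:
        warnings.warn(f"{isolated} isolated cells in the SNN graph", stacklevel=2)
    return NeighborGraph(nodes=list(nodes), modality_of=list(tags), edges=edges, k=k)


def cluster_leiden(
    graph: NeighborGraph, resolution: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Leiden joint clustering of the SNN graph.

    Returns one integer label per node; clusters are renumbered by
    decreasing size (largest = 0).  Deterministic for a fixed seed.
    """
    n = len(graph.nodes)
    if n == 0:
        raise ValidationError("empty graph")
    g = igraph.Graph(n=n, edges=[(i, j) for i, j, _ in graph.edges])
    if not graph.edges:
        warnings.warn("graph has no edges: every cell is its own cluster", stacklevel=2)
        return np.arange(n)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=[w for _, _, w in graph.edges],
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.asarray(part.membership)
    sizes = np.bincount(raw)
    # stable: ties in size keep the lower original label first
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return remap[raw]


def _knn_vote_scores(
    source_coords: np.ndarray,
    source_labels: np.ndarray,
    target_coords: np.ndarray,
    classes: np.ndarray,
    k: int = 20,
) -> np.ndarray:
    """Distance-weighted k-NN vote; rows normalized to sum to 1."""
    k = min(k, source_coords.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(source_coords)
    dist, idx = nn.kneighbors(target_coords)
    w = 1.0 / (dist + 1e-12)
    scores = np.zeros((target_coords.shape[0], len(classes)))
    class_index = {c: i for i, c in enumerate(classes)}
    for t in range(target_coords.shape[0]):
        for d, j in zip(w[t], idx[t]):
            scores[t, class_index[source_labels[j]]] += d
    return scores / scores.sum(axis=1, keepdims=True)


def transfer_labels(
    source_coords: np.ndarray,
    source_labels: CellAnnotation,
    target_coords: np.ndarray,
    target_cell_ids: list[str] | None = None,
    classifier: str = "max_margin",
    seed: int = 0,
    restrict_to: list[str] | None = None,
) -> LabelTransferResult:
    """Transfer cell-type labels across modalities in the co-embedding.

    ``max_margin`` trains a probability-calibrated RBF support vector
    machine on the source coordinates; ``knn_vote`` uses a
    distance-weighted 20-NN vote.  Either returns a normalized score
    per type (rows sum to 1); the predicted label is the argmax.
    Classes with a single cell are merged into the nearest class.

    ``restrict_to`` renormalizes the scores over a stated candidate
    label set before prediction — appropriate when the target modality
    is known to lack some source types (otherwise cells near a
    target-absent source cluster leak into its label).
    """
    src = np.asarray(source_coords, dtype=float)
    tgt = np.asarray(target_coords, dtype=float)
    if src.shape[0] != len(source_labels.cell_ids):
        raise ValidationError("source coordinates and labels disagree in length")
    labels = np.asarray(source_labels.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("label transfer needs at least 2 source classes")
    for cls in classes[counts == 1]:
        i = int(np.flatnonzero(labels == cls)[0])
        others = np.flatnonzero(labels != cls)
        d = np.linalg.norm(src[others] - src[i], axis=1)
        labels = labels.copy()
        labels[i] = labels[others[np.argmin(d)]]
        warnings.warn(
            f"class {cls!r} has a single cell; merged into {labels[i]!r}", stacklevel=2
        )
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("fewer than 2 classes remain after merging singletons")

    if classifier == "max_margin":
        model = SVC(kernel="rbf", probability=True, random_state=seed)
        model.fit(src, labels)
        scores = model.predict_proba(tgt)
        class_order = list(model.classes_)
    elif classifier == "knn_vote":
        scores = _knn_vote_scores(src, labels, tgt, classes)
        class_order = list(classes)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    if restrict_to is not None:
        missing = [t for t in restrict_to if t not in class_order]
        if missing:
            raise ValidationError(f"restrict_to types absent from source: {missing}")
        cols = [class_order.index(t) for t in restrict_to]
        scores = scores[:, cols]
        class_order = list(restrict_to)
    scores = scores / scores.sum(axis=1, keepdims=True)
    predicted = [class_order[i] for i in np.argmax(scores, axis=1)]
    ids = target_cell_ids if target_cell_ids is not None else [
        f"target{i}" for i in range(tgt.shape[0])
    ]
    return LabelTransferResult(
        predicted_labels=predicted,
        score_matrix=scores,
        type_names=[str(c) for c in class_order],
        target_cell_ids=list(ids),
    )
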