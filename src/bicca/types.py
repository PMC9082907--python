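"""Domain containers shared across the package.

The central objects mirror the mathematical setup of bi-order CCA:
``X`` (M features x K cells) and ``Y`` (N features x L cells) are two
single-cell matrices from different modalities, bridged by a modality
fusion matrix ``Z`` (M x L) that expresses Y's cells in X's feature
space.  The co-embedding consists of cell projections ``U`` (K x E) and
``S`` (L x E) plus feature loadings ``T`` (M x E) and ``V`` (N x E).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp


class ValidationError(ValueError):
    """Input violates a structural invariant (shapes, IDs, domains)."""


class FormatError(ValueError):
    """An on-disk artifact is malformed or incomplete."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} (e.g. {dup!r})")
    return ids


def _check_finite(values, what: str) -> None:
    data = values.data if sp.issparse(values) else np.asarray(values)
    if data.size and not np.all(np.isfinite(data)):
        raise ValidationError(f"{what} contains NaN/Inf entries")


@dataclass
class ModalityMatrix:
    """A feature-by-cell matrix for one modality.

    ``values`` may be dense ``ndarray`` or any scipy sparse matrix;
    sparse input is kept sparse.  Rows are features, columns are cells.
    """

    values: np.ndarray | sp.spmatrix
    feature_ids: list[str]
    cell_ids: list[str]
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.feature_ids = _check_unique(self.feature_ids, "feature IDs")
        self.cell_ids = _check_unique(self.cell_ids, "cell IDs")
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        _check_finite(self.values, "modality matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Dense float view of the values (copy only when sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def subset_features(self, index: np.ndarray) -> "ModalityMatrix":
        idx = np.asarray(index)
        return ModalityMatrix(
            values=self.values[idx, :],
            feature_ids=[self.feature_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            modality=self.modality,
        )

    def subset_cells(self, index: np.ndarray) -> "ModalityMatrix":
        idx = np.asarray(index)
        return ModalityMatrix(
            values=self.values[:, idx],
            feature_ids=list(self.feature_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            modality=self.modality,
        )


@dataclass(frozen=True)
class GeneModel:
    """One gene interval; internal coordinates are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"gene {self.gene_id}: negative start {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class CellAnnotation:
    """Per-cell type labels for one modality."""

    cell_ids: list[str]
    labels: list[str]
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "annotated cell IDs")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.cell_ids):
            raise ValidationError("one label per cell_id required")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))

    def reorder(self, cell_ids: Sequence[str]) -> "CellAnnotation":
        m = self.as_dict()
        missing = [c for c in cell_ids if c not in m]
        if missing:
            raise ValidationError(f"cells without labels: {missing[:5]}")
        return CellAnnotation(list(cell_ids), [m[c] for c in cell_ids], self.modality)


@dataclass
class FusionMatrix:
    """The M x L bridge matrix Z (or its initializer Z0).

    Rows live in X's feature space, columns are Y's cells.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense(), dtype=float)
        else:
            self.values = np.asarray(self.values, dtype=float)
        self.row_ids = _check_unique(self.row_ids, "fusion row IDs")
        self.col_ids = _check_unique(self.col_ids, "fusion column IDs")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"fusion shape {self.values.shape} does not match ID lists "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        _check_finite(self.values, "fusion matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def frobenius_norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass
class LowDimProfiles:
    """Reduced profiles used by the fast integration path.

    ``components_x`` (d x K), ``components_y`` (d' x L) and
    ``components_z`` (d x L) replace X, Y and Z0 in the solver.
    """

    components_x: np.ndarray
    components_y: np.ndarray
    components_z: np.ndarray

    @property
    def d(self) -> int:
        return self.components_x.shape[0]

    @property
    def d_prime(self) -> int:
        return self.components_y.shape[0]


@dataclass
class CoEmbedding:
    """Canonical correlation vectors of one bi-CCA state.

    All four matrices have orthonormal columns; ``canonical_correlations``
    are the cell-level singular values scaled by 1/(M-1), with the raw
    singular values kept alongside.
    """

    U: np.ndarray  # K x E cell projections of X
    S: np.ndarray  # L x E cell projections of Z / Y side
    T: np.ndarray  # M x E feature loadings, X space
    V: np.ndarray  # N x E feature loadings, Y space
    canonical_correlations: np.ndarray
    singular_values: np.ndarray

    @property
    def E(self) -> int:
        return self.U.shape[1]


@dataclass
class IntegrationResult:
    """Everything a bi-CCA run produces."""

    embedding: CoEmbedding
    fusion: FusionMatrix
    objective_trace: list[float]
    alpha: float
    lambda_: float
    n_l: float
    n_r: float
    converged: bool
    iterations: int
    iteration0: CoEmbedding | None = None
    mode: str = "full"
    seed: int | None = None
    cell_ids_x: list[str] = field(default_factory=list)
    cell_ids_y: list[str] = field(default_factory=list)
    feature_ids_x: list[str] = field(default_factory=list)
    feature_ids_y: list[str] = field(default_factory=list)
    lowdim: LowDimProfiles | None = None


@dataclass
class NeighborGraph:
    """Shared-nearest-neighbor graph over co-embedded cells."""

    nodes: list[str]
    modality_of: list[str]
    edges: list[tuple[int, int, float]]  # (i, j, weight), i < j
    k: int

    def __post_init__(self) -> None:
        for i, j, w in self.edges:
            if i == j:
                raise ValidationError("self-loop in SNN graph")
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"SNN weight {w} outside [0, 1]")


@dataclass
class LabelTransferResult:
    predicted_labels: list[str]
    score_matrix: np.ndarray  # target cells x types
    type_names: list[str]
    target_cell_ids: list[str]

    def __post_init__(self) -> None:
        rows = self.score_matrix.sum(axis=1)
        if self.score_matrix.size and not np.allclose(rows, 1.0, atol=1e-8):
            raise ValidationError("score rows must sum to 1")


@dataclass
class MetricsReport:
    silhouette_mean: float | None = None
    mixing_mean: float | None = None
    anchoring_mean: float | None = None
    accuracy_overall: float | None = None
    accuracy_micro: float | None = None
    accuracy_per_type: Mapping[str, float] = field(default_factory=dict)
    imputation_r_overall: float | None = None
    imputation_r_per_type: Mapping[str, float | None] = field(default_factory=dict)


@dataclass
class FeatureLinkSet:
    """Retained feature-feature correlation edges."""

    edges: list[tuple[str, str, float]]  # (feature_x, feature_y, r)
    cutoff: float
    top_n: int
    anchor: str = "x_features"
    n_skipped_zero_variance: int = 0


@dataclass
class SimTruth:
    """Ground truth attached to a synthetic paired dataset."""

    latent: np.ndarray  # E_true x n_cells
    loadings_x: np.ndarray  # M x E_true
    loadings_y: np.ndarray  # N x E_true
    labels: list[str]
    pairing: dict[str, str]  # X cell id -> Y cell id
    x_profiles_y_cells: np.ndarray  # M x L noiseless X-space truth for Y cells
    noise_sd: float
    dropout_rate: float
    corruption: float
    seed: int
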