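"""Synthetic paired two-modality data with known ground truth.

The generator emulates the statistical structure bi-CCA assumes: both
modalities are (noisy) linear read-outs of a shared low-dimensional
cell state.  Cell types are centroids in the latent space, each cell a
jittered draw around its centroid; the same latent vector feeds the X
and the Y feature loadings, so the two modality copies of a cell are
truly paired.  The initializer Z0 is a convex blend of the exact
cross-modality map with a random linear map of Y, which makes Z0
informative but imperfect — the axis the coupling parameter alpha is
meant to absorb.

Defaults describe the standard benchmark configuration used throughout
the test-suite: 4 balanced cell types, 300 paired cells, 500 x 800
features, 6 latent factors, unit Gaussian noise on top of
unit-variance signal, and a half-corrupted Z0.
"""

from __future__ import annotations

import numpy as np

from .types import (
    CellAnnotation,
    FusionMatrix,
    ModalityMatrix,
    SimTruth,
    ValidationError,
)

_CENTROID_SCALE = 1.0
_JITTER_SD = 0.3
_NB_DISPERSION = 10.0


def simulate_paired(
    n_cells: int = 300,
    n_types: int = 4,
    M: int = 500,
    N: int = 800,
    E_true: int = 6,
    noise_sd: float = 1.0,
    dropout_rate: float = 0.0,
    corruption: float = 0.5,
    count_model: str = "gaussian",
    seed: int = 0,
) -> tuple[ModalityMatrix, ModalityMatrix, FusionMatrix, SimTruth]:
    """Draw a paired two-modality dataset with ground truth.

    Returns ``(X, Y, Z0, truth)``: X is M x n_cells, Y is N x n_cells,
    both copies share cell states one-to-one (``truth.pairing``), and
    Z0 is the corrupted initial fusion matrix.  ``count_model='nb'``
    exponentiates the linear predictor into rates and draws
    overdispersed counts with optional dropout; ``gaussian`` keeps the
    linear model exactly (the solver's home turf).
    """
    if n_types < 1 or n_cells < n_types:
        raise ValidationError("need n_cells >= n_types >= 1")
    if E_true < max(1, n_types - 1):
        raise ValidationError(f"E_true={E_true} must be >= n_types - 1 = {n_types - 1}")
    if E_true > min(M, N):
        raise ValidationError(f"E_true={E_true} exceeds min(M, N) = {min(M, N)}")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValidationError("dropout_rate must be in [0, 1)")
    if not (0.0 <= corruption <= 1.0):
        raise ValidationError("corruption must be in [0, 1]")
    if count_model not in ("gaussian", "nb"):
        raise ValueError(f"unknown count_model {count_model!r}")
    rng = np.random.default_rng(seed)

    centroids = rng.normal(0.0, _CENTROID_SCALE, size=(E_true, n_types))
    type_of = np.repeat(np.arange(n_types), int(np.ceil(n_cells / n_types)))[:n_cells]
    latent = centroids[:, type_of] + rng.normal(0.0, _JITTER_SD, size=(E_true, n_cells))
    loadings_x = rng.normal(0.0, 1.0 / np.sqrt(E_true), size=(M, E_true))
    loadings_y = rng.normal(0.0, 1.0 / np.sqrt(E_true), size=(N, E_true))

    X_clean = loadings_x @ latent
    Y_clean = loadings_y @ latent
    if count_model == "gaussian":
        Xv = X_clean + rng.normal(0.0, noise_sd, size=X_clean.shape)
        Yv = Y_clean + rng.normal(0.0, noise_sd, size=Y_clean.shape)
    else:
        Xv = _nb_counts(X_clean, noise_sd, dropout_rate, rng)
        Yv = _nb_counts(Y_clean, noise_sd, dropout_rate, rng)

    Z_true = X_clean  # noiseless X-space profiles of the paired Y cells
    Z_rand = (rng.normal(0.0, 1.0 / np.sqrt(N), size=(M, N)) @ Y_clean)
    Z0v = (1.0 - corruption) * Z_true / np.linalg.norm(Z_true)
    if corruption > 0:
        Z0v = Z0v + corruption * Z_rand / np.linalg.norm(Z_rand)

    x_ids = [f"x{i:04d}" for i in range(n_cells)]
    y_ids = [f"y{i:04d}" for i in range(n_cells)]
    labels = [f"type{t}" for t in type_of]
    X = ModalityMatrix(Xv, [f"gene{j:04d}" for j in range(M)], x_ids, "RNA")
    Y = ModalityMatrix(Yv, [f"feat{j:04d}" for j in range(N)], y_ids, "ATAC")
    Z0 = FusionMatrix(Z0v, list(X.feature_ids), y_ids)
    truth = SimTruth(
        latent=latent,
        loadings_x=loadings_x,
        loadings_y=loadings_y,
        labels=labels,
        pairing=dict(zip(x_ids, y_ids)),
        x_profiles_y_cells=Z_true,
        noise_sd=noise_sd,
        dropout_rate=dropout_rate,
        corruption=corruption,
        seed=seed,
    )
    return X, Y, Z0, truth


def _nb_counts(
    linear: np.ndarray, noise_sd: float, dropout_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts from a linear predictor."""
    log_mu = np.clip(linear + rng.normal(0.0, noise_sd, size=linear.shape), -8, 8)
    mu = np.exp(log_mu)
    shape = _NB_DISPERSION
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(float)
    if dropout_rate > 0:
        counts *= rng.random(counts.shape) >= dropout_rate
    return counts


def _index_of(cell_id: str) -> int:
    return int(cell_id[1:])


def annotation_for(truth: SimTruth, m: ModalityMatrix) -> CellAnnotation:
    """Ground-truth cell-type labels for a (possibly subset) modality."""
    return CellAnnotation(
        list(m.cell_ids), [truth.labels[_index_of(c)] for c in m.cell_ids], m.modality
    )


def pairing_indices(
    truth: SimTruth, X: ModalityMatrix, Y: ModalityMatrix
) -> list[tuple[int, int]]:
    """Positional (X index, Y index) pairs surviving in both matrices."""
    ypos = {c: i for i, c in enumerate(Y.cell_ids)}
    pairs = []
    for i, xc in enumerate(X.cell_ids):
        yc = truth.pairing.get(xc)
        if yc is not None and yc in ypos:
            pairs.append((i, ypos[yc]))
    return pairs


def apply_imbalance(
    Y: ModalityMatrix,
    truth: SimTruth,
    scenario: str,
    frac: float = 0.5,
    types: list[str] | None = None,
    seed: int = 0,
) -> tuple[ModalityMatrix, SimTruth]:
    """Perturb the Y modality to create cell-type imbalance.

    ``downsample_major`` removes ``frac`` of the cells of the named
    types (default: the single largest type) from Y only;
    ``drop_minor`` removes the named types from Y entirely.  X is left
    untouched; the returned truth restricts the pairing and the
    ground-truth profiles to the surviving Y cells.
    """
    rng = np.random.default_rng(seed)
    y_labels = [truth.labels[_index_of(c)] for c in Y.cell_ids]
    counts: dict[str, int] = {}
    for l in y_labels:
        counts[l] = counts.get(l, 0) + 1

    if scenario == "downsample_major":
        if not (0.0 < frac <= 1.0):
            raise ValidationError("frac must be in (0, 1]")
        if types is None:
            types = [max(counts, key=lambda t: (counts[t], t))]
        keep = np.ones(Y.n_cells, dtype=bool)
        for t in types:
            members = np.flatnonzero([l == t for l in y_labels])
            n_drop = int(round(frac * len(members)))
            keep[rng.choice(members, n_drop, replace=False)] = False
    elif scenario == "drop_minor":
        if not types:
            raise ValidationError("drop_minor needs a list of types")
        missing = [t for t in types if t not in counts]
        if missing:
            import warnings

            warnings.warn(f"types absent from Y, no-op for: {missing}", stacklevel=2)
        if set(types) >= set(counts):
            raise ValidationError("cannot drop every cell type from Y")
        keep = np.array([l not in set(types) for l in y_labels])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    kept_idx = np.flatnonzero(keep)
    Y2 = Y.subset_cells(kept_idx)
    surviving = set(Y2.cell_ids)
    truth2 = SimTruth(
        latent=truth.latent,
        loadings_x=truth.loadings_x,
        loadings_y=truth.loadings_y,
        labels=list(truth.labels),
        pairing={x: y for x, y in truth.pairing.items() if y in surviving},
        x_profiles_y_cells=truth.x_profiles_y_cells[:, kept_idx],
        noise_sd=truth.noise_sd,
        dropout_rate=truth.dropout_rate,
        corruption=truth.corruption,
        seed=truth.seed,
    )
    return Y2, truth2


def subset_fusion_cells(Z0: FusionMatrix, Y: ModalityMatrix) -> FusionMatrix:
    """Restrict a fusion matrix to the cells present in Y."""
    idx = [Z0.col_ids.index(c) for c in Y.cell_ids]
    return FusionMatrix(Z0.values[:, idx], list(Z0.row_ids), list(Y.cell_ids))
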