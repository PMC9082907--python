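"""The bi-order CCA solver.

Two matrices X (M features x K cells) and Y (N features x L cells)
with unpaired cells and unmatched features are coupled through a
modality fusion matrix Z (M x L) expressing Y's cells in X's feature
space.  The solver alternates three convex subproblems:

1. cell-level CCVs: (U, S) = first E singular vector pairs of X'Z;
2. feature-level CCVs: (T, V) = first E singular vector pairs of Z Y';
3. fusion update:
       Z := (1 - a) { (1 - l)/n_l  X U S'  +  l/n_r  T V' Y } + a Z0,
   followed by projection to unit Frobenius norm,

maximizing

    (1 - a) tr{ (1-l)/n_l (XU)' Z S + l/n_r (Z'T)' Y'V } - a ||Z - Z0||_F^2

subject to orthonormal U, S, T, V and ||Z||_F = 1.  ``a`` (alpha,
0 <= a < 1) anchors Z to its initializer Z0; ``l`` (lambda, 0..1)
balances the cell-level and feature-level objectives; n_l, n_r are
scale factors fixed from the iteration-0 CCVs.  The CCA here is the
diagonal-covariance variant: CCVs are singular vectors of the plain
cross-product of row-standardized matrices, with no within-set
whitening.

A fast path runs the identical iteration on low-dimension profiles
(P_X, P_Y, P_z) obtained from an initial CCA of (X, Z0) and an SVD of
Y, so peak cost is independent of the raw feature counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from .preprocess import _deterministic_svd, standardize_fusion
from .types import (
    CoEmbedding,
    FusionMatrix,
    IntegrationResult,
    LowDimProfiles,
    ModalityMatrix,
    ValidationError,
)

logger = logging.getLogger("bicca")

_VAR_FLOOR = 1e-8
_DENSE_SVD_MAX = 400  # min(shape) below this -> exact dense SVD


def standardize_rows(
    A: np.ndarray | sp.spmatrix, var_floor: float = _VAR_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each feature row; drop (near-)constant rows.

    Returns the standardized dense matrix and the boolean mask of kept
    rows.  Cells with all-zero profiles are rejected.
    """
    dense = np.asarray(A.todense(), dtype=float) if sp.issparse(A) else np.asarray(A, dtype=float)
    col_norm = np.linalg.norm(dense, axis=0)
    if np.any(col_norm == 0):
        bad = np.flatnonzero(col_norm == 0)
        raise ValidationError(f"cells with all-zero profiles at columns {bad[:5].tolist()}")
    mu = dense.mean(axis=1, keepdims=True)
    var = dense.var(axis=1)
    keep = var >= var_floor
    if not np.any(keep):
        raise ValidationError("no usable features: all rows are (near-)constant")
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} (near-)constant feature rows before CCA",
            stacklevel=2,
        )
    out = (dense[keep] - mu[keep]) / np.sqrt(var[keep])[:, None]
    return out, keep


def cross_product(
    A: np.ndarray, B: np.ndarray, block_size: int | None = None
) -> np.ndarray:
    """A'B accumulated over feature blocks of ``block_size`` rows.

    Peak extra memory is bounded by the block, not by the shared
    feature count; with ``block_size`` None the product is unblocked.
    """
    if A.shape[0] != B.shape[0]:
        raise ValidationError(
            f"cross-product needs a shared feature axis: {A.shape[0]} vs {B.shape[0]}"
        )
    if block_size is None or block_size >= A.shape[0]:
        return A.T @ B
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    out = np.zeros((A.shape[1], B.shape[1]))
    for lo in range(0, A.shape[0], block_size):
        hi = lo + block_size
        out += A[lo:hi].T @ B[lo:hi]
    return out


def _truncated_svd(
    Sigma: np.ndarray, E: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First E singular triplets with deterministic signs.

    Exact dense SVD for small problems; seeded randomized SVD above
    ``_DENSE_SVD_MAX`` (agrees with dense to ~1e-6 on test sizes).
    """
    if min(Sigma.shape) <= _DENSE_SVD_MAX or E >= min(Sigma.shape) - 1:
        W, s, Vt = _deterministic_svd(Sigma, min(E, min(Sigma.shape)))
        return W, s, Vt
    W, s, Vt = randomized_svd(
        Sigma, n_components=E, n_iter=7, random_state=seed if seed is not None else 0
    )
    for j in range(W.shape[1]):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
            Vt[j, :] = -Vt[j, :]
    return W, s, Vt


def fit_cca_pair(
    A: np.ndarray,
    B: np.ndarray,
    E: int,
    block_size: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlation vectors of (A, B) sharing the feature axis.

    Returns ``(left, right, correlations, singular_values)`` where left
    and right are the first E left/right singular vectors of Sigma =
    A'B and correlations are the singular values scaled by 1/(M - 1)
    (M = shared feature count).  E above the rank of Sigma is truncated
    to the rank with a warning.
    """
    if E < 1:
        raise ValidationError(f"E must be positive, got {E}")
    if E > min(A.shape[1], B.shape[1]):
        raise ValidationError(
            f"E={E} exceeds min cell counts ({A.shape[1]}, {B.shape[1]})"
        )
    Sigma = cross_product(A, B, block_size)
    W, s, Vt = _truncated_svd(Sigma, E, seed)
    tol = max(Sigma.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < len(s):
        warnings.warn(
            f"E={len(s)} exceeds rank {rank} of the cross-product; truncating",
            stacklevel=2,
        )
        W, s, Vt = W[:, :rank], s[:rank], Vt[:rank, :]
    if rank == 0:
        raise ValidationError("degenerate cross-product: all singular values are zero")
    M = A.shape[0]
    corr = s / (M - 1) if M > 1 else s.copy()
    return W, Vt.T, corr, s


def compute_scale_factors(
    X: np.ndarray,
    Y: np.ndarray,
    U0: np.ndarray,
    S0: np.ndarray,
    T0: np.ndarray,
    V0: np.ndarray,
) -> tuple[float, float]:
    """Scale factors n_l = ||X U0 S0'||_F^2, n_r = ||T0 V0' Y||_F^2.

    The CCVs come from the iteration-0 fits on (X, Z0) and (Z0, Y).
    """
    n_l = float(np.linalg.norm(X @ U0 @ S0.T) ** 2)
    n_r = float(np.linalg.norm(T0 @ (V0.T @ Y)) ** 2)
    if n_l <= 0 or n_r <= 0:
        raise ValidationError(
            "zero scale factor: degenerate CCVs; try a larger E or check Z0"
        )
    return n_l, n_r


def update_fusion_matrix(
    X: np.ndarray,
    Y: np.ndarray,
    U: np.ndarray,
    S: np.ndarray,
    T: np.ndarray,
    V: np.ndarray,
    Z0: np.ndarray,
    alpha: float,
    lambda_: float,
    n_l: float,
    n_r: float,
) -> np.ndarray:
    """One fusion-matrix update followed by unit-Frobenius projection.

    Z := (1-a){ (1-l)/n_l X U S' + l/n_r T V' Y } + a Z0, then
    Z := Z / ||Z||_F.  The three parts are the X-side reconstruction,
    the Y-side reconstruction, and the anchored initializer.
    """
    _check_params(alpha, lambda_)
    M, L = Z0.shape
    left = X @ U @ S.T
    if left.shape != (M, L):
        raise ValidationError(f"X U S' has shape {left.shape}, expected {(M, L)}")
    right = T @ (V.T @ Y)
    if right.shape != (M, L):
        raise ValidationError(f"T V' Y has shape {right.shape}, expected {(M, L)}")
    Z = (1.0 - alpha) * ((1.0 - lambda_) / n_l * left + lambda_ / n_r * right) + alpha * Z0
    norm = np.linalg.norm(Z)
    if norm == 0:
        raise ValidationError("fusion update produced an all-zero matrix")
    return Z / norm


def evaluate_objective(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    Z0: np.ndarray,
    U: np.ndarray,
    S: np.ndarray,
    T: np.ndarray,
    V: np.ndarray,
    alpha: float,
    lambda_: float,
    n_l: float,
    n_r: float,
) -> float:
    """The weighted bi-CCA objective with the Z0 anchoring penalty."""
    _check_params(alpha, lambda_)
    left = float(np.trace((X @ U).T @ Z @ S))
    right = float(np.trace((Z.T @ T).T @ (Y.T @ V)))
    penalty = float(np.linalg.norm(Z - Z0) ** 2)
    return (1.0 - alpha) * ((1.0 - lambda_) / n_l * left + lambda_ / n_r * right) - alpha * penalty


def monitored_objective(
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    Z0: np.ndarray,
    U: np.ndarray,
    S: np.ndarray,
    T: np.ndarray,
    V: np.ndarray,
    alpha: float,
    lambda_: float,
    n_l: float,
    n_r: float,
) -> float:
    """The potential function the alternating iteration provably ascends.

    On the unit sphere ||Z||_F = 1 the fusion update (add alpha Z0,
    renormalize) is the exact maximizer of the objective whose
    quadratic anchoring penalty carries weight alpha/2 — completing
    the square turns -(alpha/2)||Z - Z0||^2 into a linear term with
    coefficient alpha, matching the update.  The trace and the
    convergence test therefore monitor this potential; it coincides
    with :func:`evaluate_objective` when alpha = 0.
    """
    _check_params(alpha, lambda_)
    left = float(np.trace((X @ U).T @ Z @ S))
    right = float(np.trace((Z.T @ T).T @ (Y.T @ V)))
    penalty = float(np.linalg.norm(Z - Z0) ** 2)
    return (
        (1.0 - alpha) * ((1.0 - lambda_) / n_l * left + lambda_ / n_r * right)
        - 0.5 * alpha * penalty
    )


def _check_params(alpha: float, lambda_: float) -> None:
    if not (0.0 <= alpha < 1.0):
        raise ValidationError(f"alpha must satisfy 0 <= alpha < 1, got {alpha}")
    if not (0.0 <= lambda_ <= 1.0):
        raise ValidationError(f"lambda must satisfy 0 <= lambda <= 1, got {lambda_}")


@dataclass
class _LoopState:
    embedding: CoEmbedding
    iteration0: CoEmbedding
    Z: np.ndarray
    trace: list[float]
    n_l: float
    n_r: float
    converged: bool
    iterations: int


def _bicca_loop(
    Xs: np.ndarray,
    Ys: np.ndarray,
    Z0s: np.ndarray,
    E: int,
    alpha: float,
    lambda_: float,
    tol: float,
    max_iter: int,
    block_size: int | None,
    seed: int | None,
) -> _LoopState:
    """Alternating solver on prepared (standardized) matrices."""
    M = Xs.shape[0]

    def ccvs(Z: np.ndarray) -> CoEmbedding:
        U, S, corr, sv = fit_cca_pair(Xs, Z, E, block_size, seed)
        T, V, _, _ = fit_cca_pair(Z.T, Ys.T, E, block_size, seed)
        return CoEmbedding(U=U, S=S, T=T, V=V, canonical_correlations=corr, singular_values=sv)

    Z = Z0s.copy()
    emb = ccvs(Z)
    it0 = emb
    n_l, n_r = compute_scale_factors(Xs, Ys, emb.U, emb.S, emb.T, emb.V)
    f_prev = monitored_objective(
        Xs, Ys, Z, Z0s, emb.U, emb.S, emb.T, emb.V, alpha, lambda_, n_l, n_r
    )
    trace = [f_prev]
    logger.info("iter=0 objective=%.6g delta=nan", f_prev)
    converged = False
    iterations = 0
    for t in range(1, max_iter + 1):
        Z = update_fusion_matrix(
            Xs, Ys, emb.U, emb.S, emb.T, emb.V, Z0s, alpha, lambda_, n_l, n_r
        )
        emb = ccvs(Z)
        f = monitored_objective(
            Xs, Ys, Z, Z0s, emb.U, emb.S, emb.T, emb.V, alpha, lambda_, n_l, n_r
        )
        if not np.isfinite(f):
            raise RuntimeError(
                f"non-finite objective at iteration {t}; check inputs for "
                "degenerate scaling"
            )
        delta = abs(f - f_prev) / (abs(f_prev) + 1e-12)
        trace.append(f)
        iterations = t
        logger.info("iter=%d objective=%.6g delta=%.3g", t, f, delta)
        if delta < tol:
            converged = True
            break
        f_prev = f
    return _LoopState(emb, it0, Z, trace, n_l, n_r, converged, iterations)


def run_bicca(
    X: ModalityMatrix,
    Y: ModalityMatrix,
    Z0: FusionMatrix,
    E: int | None = None,
    alpha: float = 0.1,
    lambda_: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 50,
    mode: str = "full",
    dims_lowdim: tuple[int, int] | None = None,
    block_size: int = 1000,
    seed: int | None = 0,
) -> IntegrationResult:
    """Run bi-CCA on two modality matrices bridged by Z0.

    Z0's rows must cover X's features and its columns Y's cells (they
    are aligned by ID).  Feature rows of X and Y are z-scored, with
    (near-)constant rows dropped; Z0 is scaled to unit Frobenius norm.
    ``mode='lowdim'`` runs the identical iteration on low-dimension
    profiles (initial CCA of (X, Z0) for P_X/P_z0, SVD of Y for P_Y)
    with dimensionalities ``dims_lowdim`` (default (50, 50) capped by
    the data).  The iteration-0 embedding, which coincides with a
    classical CCA of (X, Z0), is exposed on the result.
    """
    if mode not in ("full", "lowdim"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_params(alpha, lambda_)

    if list(Z0.row_ids) != list(X.feature_ids) or list(Z0.col_ids) != list(Y.cell_ids):
        try:
            ridx = [Z0.row_ids.index(f) for f in X.feature_ids]
            cidx = [Z0.col_ids.index(c) for c in Y.cell_ids]
        except ValueError as e:
            raise ValidationError(
                "Z0 does not cover X's features and Y's cells"
            ) from e
        Z0 = FusionMatrix(
            Z0.values[np.ix_(ridx, cidx)], list(X.feature_ids), list(Y.cell_ids)
        )

    Xs, keep_x = standardize_rows(X.values)
    Ys, keep_y = standardize_rows(Y.values)
    Z0rows = np.asarray(Z0.values[keep_x], dtype=float)
    # z-score Z0's feature rows like X's and Y's, so both sides of the
    # cross-products live on one scale; constant rows are centered only
    mu = Z0rows.mean(axis=1, keepdims=True)
    sd = Z0rows.std(axis=1, keepdims=True)
    Z0rows = (Z0rows - mu) / np.where(sd < np.sqrt(_VAR_FLOOR), 1.0, sd)
    Z0v = standardize_fusion(
        FusionMatrix(
            Z0rows, [f for f, k in zip(Z0.row_ids, keep_x) if k], list(Z0.col_ids)
        )
    ).values

    K, L = Xs.shape[1], Ys.shape[1]
    max_E = min(K, L, Xs.shape[0], Ys.shape[0])
    if E is None:
        E = min(30, max_E - 1) if max_E > 1 else 1
    if E > max_E:
        raise ValidationError(f"E={E} exceeds the usable rank bound {max_E}")

    lowdim = None
    if mode == "full":
        state = _bicca_loop(
            Xs, Ys, Z0v, E, alpha, lambda_, tol, max_iter, block_size, seed
        )
        fusion = FusionMatrix(
            state.Z, [f for f, k in zip(X.feature_ids, keep_x) if k], list(Y.cell_ids)
        )
    else:
        d, d_prime = dims_lowdim or (50, 50)
        d = min(d, min(Xs.shape), Z0v.shape[1])
        d_prime = min(d_prime, min(Ys.shape))
        if E > min(d, d_prime):
            raise ValidationError(f"E={E} exceeds lowdim dims ({d}, {d_prime})")
        U0, S0, _, sv = fit_cca_pair(Xs, Z0v, d, block_size, seed)
        d = len(sv)
        P_X = sv[:, None] * U0.T  # d x K
        P_z0 = sv[:, None] * S0.T  # d x L
        W, sy, Vt = _truncated_svd(Ys, d_prime, seed)
        P_Y = sy[:, None] * Vt  # d' x L
        P_z0 = P_z0 / np.linalg.norm(P_z0)
        state = _bicca_loop(
            P_X, P_Y, P_z0, E, alpha, lambda_, tol, max_iter, block_size, seed
        )
        lowdim = LowDimProfiles(components_x=P_X, components_y=P_Y, components_z=state.Z)
        fusion = FusionMatrix(
            state.Z, [f"cc{i + 1}" for i in range(state.Z.shape[0])], list(Y.cell_ids)
        )

    return IntegrationResult(
        embedding=state.embedding,
        fusion=fusion,
        objective_trace=state.trace,
        alpha=alpha,
        lambda_=lambda_,
        n_l=state.n_l,
        n_r=state.n_r,
        converged=state.converged,
        iterations=state.iterations,
        iteration0=state.iteration0,
        mode=mode,
        seed=seed,
        cell_ids_x=list(X.cell_ids),
        cell_ids_y=list(Y.cell_ids),
        feature_ids_x=[f for f, k in zip(X.feature_ids, keep_x) if k],
        feature_ids_y=[f for f, k in zip(Y.feature_ids, keep_y) if k],
        lowdim=lowdim,
    )


def impute_fusion_profiles(
    result: IntegrationResult,
    X: ModalityMatrix,
    Y: ModalityMatrix,
    Z0: FusionMatrix | None = None,
    impute_mode: str = "reconstruct",
) -> FusionMatrix:
    """Full-feature imputed X-space profiles for Y's cells.

    In full mode this is exactly the final Z of the run.  In lowdim
    mode the reduced P_z is back-projected to feature space through the
    least-squares feature loadings of the initial (X, Z0) CCA
    (``reconstruct``), or rebuilt from the X side only as X U S'
    (``cell-blend``); either result is Frobenius-standardized.
    """
    if result.mode == "full":
        return result.fusion
    if result.lowdim is None:
        raise ValidationError("lowdim profiles missing from result; run run_bicca first")
    Xs, keep_x = standardize_rows(X.values)
    row_ids = [f for f, k in zip(X.feature_ids, keep_x) if k]
    if impute_mode == "reconstruct":
        P_X = result.lowdim.components_x
        # F: least-squares map with X ~ F P_X
        F = Xs @ np.linalg.pinv(P_X)
        Z = F @ result.lowdim.components_z
    elif impute_mode == "cell-blend":
        Z = Xs @ result.embedding.U @ result.embedding.S.T
        if Z0 is not None:
            Z0v = standardize_fusion(
                FusionMatrix(Z0.values[keep_x], row_ids, list(Z0.col_ids))
            ).values
            Z = (1.0 - result.alpha) * Z / np.linalg.norm(Z) + result.alpha * Z0v
    else:
        raise ValueError(f"unknown impute_mode {impute_mode!r}")
    return standardize_fusion(FusionMatrix(Z, row_ids, list(Y.cell_ids)))
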