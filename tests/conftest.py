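import numpy as np
import pytest

import bicca
from bicca.core import standardize_rows
from bicca.synth import annotation_for, pairing_indices
from bicca.types import CellAnnotation


@pytest.fixture(scope="session")
def small_sim():
    """Tiny noiseless-ish paired dataset for fast solver checks."""
    return bicca.simulate_paired(
        n_cells=50, n_types=3, M=60, N=80, E_true=5, noise_sd=0.0,
        corruption=0.3, seed=11,
    )


@pytest.fixture(scope="session")
def benchmark_sim():
    """The standard benchmark configuration: 4 balanced types, 300
    paired cells, 500 x 800 features, 6 latent factors, unit noise,
    half-corrupted Z0."""
    return bicca.simulate_paired(
        n_cells=300, n_types=4, M=500, N=800, E_true=6, noise_sd=1.0,
        corruption=0.5, seed=0,
    )


@pytest.fixture(scope="session")
def benchmark_run(benchmark_sim):
    X, Y, Z0, truth = benchmark_sim
    res = bicca.run_bicca(X, Y, Z0, E=6, alpha=0.1, lambda_=0.5, seed=0)
    return res


def standardized_truth(X, res, truth):
    """Ground-truth X-space profiles of Y's cells, row-standardized to
    the feature scale the solver works on (kept features only)."""
    keep = np.isin(X.feature_ids, res.feature_ids_x)
    Zt = truth.x_profiles_y_cells[keep]
    mu = Zt.mean(axis=1, keepdims=True)
    sd = Zt.std(axis=1, keepdims=True)
    return (Zt - mu) / np.where(sd == 0, 1.0, sd)


def standardized_z0(X, res, Z0):
    """Z0 exactly as the solver used it (row z-score + unit Frobenius)."""
    keep = np.isin(X.feature_ids, res.feature_ids_x)
    Zr = np.asarray(Z0.values[keep], dtype=float)
    mu = Zr.mean(axis=1, keepdims=True)
    sd = Zr.std(axis=1, keepdims=True)
    Zr = (Zr - mu) / np.where(sd < 1e-4, 1.0, sd)
    return Zr / np.linalg.norm(Zr)


def transfer_accuracy(res, X, Y, truth, classifier="max_margin", seed=0):
    """Macro label-transfer accuracy X -> Y in the co-embedding."""
    coords, ids, tags = bicca.joint_coordinates(res)
    n = len(res.cell_ids_x)
    lt = bicca.transfer_labels(
        coords[:n], annotation_for(truth, X), coords[n:],
        target_cell_ids=res.cell_ids_y, classifier=classifier, seed=seed,
    )
    predicted = CellAnnotation(lt.target_cell_ids, lt.predicted_labels, "y")
    per_type, macro, micro = bicca.label_transfer_accuracy(
        annotation_for(truth, Y), predicted
    )
    return per_type, macro, micro


def anchoring_pair(res, X, Y, truth):
    """(converged, iteration-0) mean anchoring distances."""
    coords, _, _ = bicca.joint_coordinates(res)
    n = len(res.cell_ids_x)
    pairs = pairing_indices(truth, X, Y)
    after = bicca.anchoring_distance_mean(coords[:n], coords[n:], pairs)
    it0 = bicca.l2_normalize(res.iteration0)
    before = bicca.anchoring_distance_mean(it0.U, it0.S, pairs)
    return after, before
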