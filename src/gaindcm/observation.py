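"""EEG observation model: lead field and spatial-mode reduction.

Superficial-pyramidal depolarisation at each source is mapped linearly
to sensors through a fixed lead field.  For inversion, sensor data are
reduced to a small number of orthonormal spatial modes — the leading
eigenvectors of the covariance of the data predicted under the prior —
so that model fitting and free-energy evaluation operate in an
8-dimensional mode space rather than over all channels.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

DEFAULT_N_SENSORS = 32
DEFAULT_N_MODES = 8
#: cap on pairwise column alignment of the synthetic lead field
MAX_COLUMN_COS = 0.6


def make_leadfield(
    n_sensors: int = DEFAULT_N_SENSORS,
    n_sources: int = 8,
    rng: Optional[np.random.Generator] = None,
    max_cos: float = MAX_COLUMN_COS,
) -> np.ndarray:
    """Synthetic lead field: seeded Gaussian columns with bounded mixing.

    Columns are unit-norm; pairs with |cosine| above ``max_cos`` are
    redrawn so sources remain spatially distinguishable, mimicking the
    mixing of a volume-conductor forward model without head geometry.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    for _ in range(1000):
        L = rng.standard_normal((n_sensors, n_sources))
        L /= np.linalg.norm(L, axis=0, keepdims=True)
        G = np.abs(L.T @ L) - np.eye(n_sources)
        if G.max() <= max_cos:
            if np.linalg.matrix_rank(L) == n_sources:
                return L
    raise RuntimeError("could not draw a lead field meeting the mixing bound")


def project_to_sensors(source_responses: np.ndarray, leadfield: np.ndarray) -> np.ndarray:
    """Apply the lead field per time point and condition.

    ``source_responses`` has shape (n_sources, T[, C]); the result has
    shape (n_sensors, T[, C]).
    """
    source_responses = np.asarray(source_responses, dtype=float)
    leadfield = np.asarray(leadfield, dtype=float)
    if source_responses.shape[0] != leadfield.shape[1]:
        raise ValueError(
            f"lead field expects {leadfield.shape[1]} sources, "
            f"got {source_responses.shape[0]}"
        )
    return np.tensordot(leadfield, source_responses, axes=(1, 0))


def compute_modes(covariance: np.ndarray, n_modes: int = DEFAULT_N_MODES) -> np.ndarray:
    """Leading eigenvectors (rows) of a sensor covariance matrix.

    Rows are orthonormal, ordered by descending eigenvalue, with sign
    fixed so each row's largest-magnitude entry is positive.  Requesting
    more modes than the numerical rank of the covariance is rejected.
    """
    C = np.asarray(covariance, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be square")
    if n_modes > C.shape[0]:
        raise ValueError("n_modes exceeds the number of sensors")
    C = 0.5 * (C + C.T)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(C.shape[0], 1) * np.finfo(float).eps * max(evals.max(), 0.0)
    rank = int(np.sum(evals > tol))
    if n_modes > rank:
        raise ValueError(
            f"n_modes={n_modes} exceeds covariance rank {rank}"
        )
    modes = evecs[:, :n_modes].T
    # deterministic sign: largest-|entry| of each row positive
    for row in modes:
        i = np.argmax(np.abs(row))
        if row[i] < 0:
            row *= -1.0
    return modes


def predicted_covariance(
    forward,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    fd_step: float = 1e-3,
) -> np.ndarray:
    """Sensor covariance of data predicted under the prior.

    First-order propagation around the prior mean: the covariance of
    the prior-mean prediction over time/conditions plus the scatter
    ``J diag(prior_var) J^T`` induced by prior parameter uncertainty,
    with sensitivities ``J`` from central finite differences.
    ``forward`` must predict in sensor space (no mode projection).
    """
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)
    p = prior_mean.size
    steps = np.eye(p) * fd_step
    thetas = np.vstack([prior_mean, prior_mean + steps, prior_mean - steps])
    pred = forward.predict(thetas)  # (2p+1, n_sens, T, C)
    n_sens = pred.shape[1]
    y0 = pred[0].reshape(n_sens, -1)
    C = (y0 @ y0.T) / y0.shape[1]
    for k in range(p):
        Jk = (pred[1 + k] - pred[1 + p + k]).reshape(n_sens, -1) / (2 * fd_step)
        C += prior_var[k] * (Jk @ Jk.T) / y0.shape[1]
    return C


def empirical_covariance(sensor_data: np.ndarray) -> np.ndarray:
    """Covariance over time/conditions(/subjects) of sensor-space data."""
    X = np.asarray(sensor_data, dtype=float)
    X = X.reshape(X.shape[0], -1)
    return (X @ X.T) / X.shape[1]


def reduce(sensor_data: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """Project sensor data (n_sensors, T[, C]) onto spatial modes."""
    sensor_data = np.asarray(sensor_data, dtype=float)
    modes = np.asarray(modes, dtype=float)
    if sensor_data.shape[0] != modes.shape[1]:
        raise ValueError(
            f"modes expect {modes.shape[1]} sensors, got {sensor_data.shape[0]}"
        )
    return np.tensordot(modes, sensor_data, axes=(1, 0))
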