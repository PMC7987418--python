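"""Gaussian RBF network with exact-interpolation training.

Every training input becomes a hidden-unit center; all units share one
Gaussian width derived from a user-facing ``spread`` parameter, and the
output weights solve the resulting linear interpolation system.  This
mirrors the classical exact-design routine (one hidden unit per sample,
zero training error on full-rank designs): the network is
y(x) = sum_j w_j exp(-||x - C_j||^2 / (2 sigma^2)).

``spread`` is the distance from a center at which a hidden unit's
activation has fallen to 0.5, which fixes sigma = spread / (0.8326 *
sqrt(2)) since exp(-0.8326^2) ~= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lstsq
from scipy.spatial.distance import cdist

from .signal import InvalidInputError

__all__ = ["RbfModel", "train_exact", "predict", "SPREAD_TO_SIGMA"]

# activation exp(-(0.8326)^2) = 0.4999... at distance `spread`
SPREAD_TO_SIGMA = 1.0 / (0.8326 * np.sqrt(2.0))


@dataclass
class RbfModel:
    """Trained network: centers (P x d), shared width sigma, weights (P,)."""

    centers: np.ndarray
    sigma: float
    weights: np.ndarray
    spread: float

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    @property
    def dim(self) -> int:
        return self.centers.shape[1]


def _design_matrix(X: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    sq = cdist(X, centers, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma * sigma))


def train_exact(X: np.ndarray, y: np.ndarray, spread: float) -> RbfModel:
    """Fit an exact-interpolation RBF network.

    Centers are the training inputs themselves; weights solve
    H w = y in the least-squares sense, where H_ij is the Gaussian
    activation of center j at input i.  On a numerically full-rank H
    this interpolates the training targets exactly; an ill-conditioned H
    (very large spread, duplicate inputs) falls back to the minimum-norm
    solution with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise InvalidInputError(f"{X.shape[0]} inputs but {y.size} targets")
    if X.shape[0] < 1:
        raise InvalidInputError("need at least one training pair")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidInputError("non-finite training data")
    if not spread > 0:
        raise InvalidInputError("spread must be positive")

    sigma = spread * SPREAD_TO_SIGMA
    H = _design_matrix(X, X, sigma)
    w, _, rank, _ = lstsq(H, y, lapack_driver="gelsy")
    if rank < H.shape[0]:
        warnings.warn(
            f"ill-conditioned RBF design matrix (rank {rank}/{H.shape[0]}); "
            "least-squares solution used",
            RuntimeWarning,
            stacklevel=2,
        )
    return RbfModel(centers=X.copy(), sigma=float(sigma), weights=w, spread=float(spread))


def predict(model: RbfModel, X: np.ndarray) -> np.ndarray:
    """Evaluate the network at each query row (deterministic)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.dim:
        raise InvalidInputError(
            f"query dimension {X.shape[1]} != model dimension {model.dim}"
        )
    return _design_matrix(X, model.centers, model.sigma) @ model.weights
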