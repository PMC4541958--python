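"""Radial-basis-function network classifier with a single coded output.

Topology is input - hidden - 1: Gaussian hidden units around k-means cluster
centers, and one linear output neuron regressed onto the numeric class codes
1..4 ("64-32-1" with 16 FFT magnitudes per electrode, "18-13-1" with landmark
features).  Training is non-iterative:

1. optional z-scoring from training statistics (FFT magnitudes span orders of
   magnitude; unscaled distances would be dominated by the DC term);
2. k-means clustering of the training features — Lloyd's algorithm with a
   seeded deterministic maximin ("farthest point") initialization; an empty
   cluster is repaired by moving its centre to the point farthest from its
   assigned centre;
3. the common Gaussian spread sigma = overlap_coefficient x mean distance
   over all distinct unordered pairs of centres (overlap coefficient 1.5 by
   default);
4. hidden activations phi_j(x) = exp(-||x - c_j||^2 / (2 sigma^2)); output
   weights (plus a bias) solve the least-squares regression of the
   activations onto the class codes.

Prediction decodes the continuous output to the nearest code in {1, 2, 3, 4},
ties toward the lower code.  Leave-one-out cross-validation retrains the
whole network (clustering included, with a fold-derived seed) on each n-1
subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .data import ConfusionMatrix

CLASS_CODES = np.array([1, 2, 3, 4])


@dataclass(frozen=True)
class RBFConfig:
    """Hyperparameters of the network: 32 hidden units for 64 FFT features,
    13 for 18 landmark features."""

    n_hidden: int = 32
    overlap_coefficient: float = 1.5
    seed: int = 0
    max_kmeans_iterations: int = 100
    scaling: str = "zscore"  # "zscore" | "none"

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.overlap_coefficient <= 0:
            raise ValueError("overlap_coefficient must be positive")
        if self.scaling not in ("zscore", "none"):
            raise ValueError("scaling must be 'zscore' or 'none'")


@dataclass
class RBFModel:
    centers: np.ndarray  # (k, p) in scaled feature space
    spread: float
    weights: np.ndarray  # (k + 1,), last entry is the bias
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    config: RBFConfig


def _kmeans(
    X: np.ndarray, k: int, seed: int, max_iter: int
) -> np.ndarray:
    """Deterministic Lloyd's k-means; returns the (k, p) centre matrix."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    # maximin initialization: random first centre, then farthest-point
    chosen = [int(rng.integers(n))]
    dist = cdist(X, X[chosen[-1]][None]).ravel()
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))  # ties -> lowest index
        chosen.append(nxt)
        dist = np.minimum(dist, cdist(X, X[nxt][None]).ravel())
    centers = X[chosen].astype(float).copy()

    assign = np.full(n, -1)
    for _ in range(max_iter):
        d = cdist(X, centers)
        new_assign = np.argmin(d, axis=1)
        # empty-cluster repair: move the centre to the point farthest from
        # its assigned centre, then reassign
        for j in range(k):
            if not np.any(new_assign == j):
                far = int(np.argmax(d[np.arange(n), new_assign]))
                centers[j] = X[far]
                d = cdist(X, centers)
                new_assign = np.argmin(d, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            centers[j] = X[assign == j].mean(axis=0)
    return centers


def _activations(X: np.ndarray, centers: np.ndarray, spread: float) -> np.ndarray:
    d2 = cdist(X, centers, metric="sqeuclidean")
    phi = np.exp(-d2 / (2.0 * spread**2))
    return np.hstack([phi, np.ones((X.shape[0], 1))])


def train(
    features: np.ndarray, class_codes: np.ndarray, config: RBFConfig
) -> RBFModel:
    """Fit centres, spread and least-squares output weights."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(class_codes, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n, p) with one code per row")
    n = X.shape[0]
    if n < config.n_hidden:
        raise ValueError(
            f"n_hidden={config.n_hidden} exceeds training size {n}"
        )
    if not np.all(np.isin(class_codes, CLASS_CODES)):
        raise ValueError("class codes must lie in {1, 2, 3, 4}")

    if config.scaling == "zscore":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale

    if config.n_hidden == n:
        centers = Z.copy()  # exact-interpolation regime
    else:
        centers = _kmeans(Z, config.n_hidden, config.seed, config.max_kmeans_iterations)

    if config.n_hidden > 1:
        spread = config.overlap_coefficient * float(pdist(centers).mean())
    else:
        # single centre: fall back to the data scale around it
        spread = config.overlap_coefficient * max(
            float(cdist(Z, centers).mean()), 1.0
        )
    if spread == 0.0:
        raise ValueError("degenerate model: all cluster centres coincide")

    phi = _activations(Z, centers, spread)
    weights, *_ = np.linalg.lstsq(phi, y, rcond=None)
    return RBFModel(
        centers=centers,
        spread=spread,
        weights=weights,
        feature_mean=mean,
        feature_scale=scale,
        config=config,
    )


def decode(outputs: np.ndarray) -> np.ndarray:
    """Map continuous outputs to the nearest code in {1..4}, ties downward."""
    out = np.asarray(outputs, dtype=float)
    codes = np.ceil(out - 0.5)  # nearest integer, .5 breaks toward the lower
    return np.clip(codes, 1, 4).astype(int)


def predict(model: RBFModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous outputs and decoded class codes for new samples."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.feature_mean.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension "
            f"{model.feature_mean.size}"
        )
    Z = (X - model.feature_mean) / model.feature_scale
    out = _activations(Z, model.centers, model.spread) @ model.weights
    return out, decode(out)


def loocv(
    features: np.ndarray, class_codes: np.ndarray, config: RBFConfig
) -> tuple[ConfusionMatrix, np.ndarray]:
    """Leave-one-out cross-validation with full per-fold retraining.

    Each fold reruns scaling, clustering (with a fold-derived seed) and the
    weight solve on the remaining n-1 samples.  Returns the accumulated
    confusion matrix (canonical class-code order) and per-fold predicted
    codes aligned with the input rows.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(class_codes, dtype=int)
    n = X.shape[0]
    if n < config.n_hidden + 1:
        raise ValueError("need at least n_hidden + 1 samples for LOOCV")
    predicted = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_cfg = RBFConfig(
            n_hidden=config.n_hidden,
            overlap_coefficient=config.overlap_coefficient,
            seed=(config.seed + 1000003 * i) % (2**31),
            max_kmeans_iterations=config.max_kmeans_iterations,
            scaling=config.scaling,
        )
        try:
            model = train(X[mask], y[mask], fold_cfg)
        except ValueError as err:
            raise RuntimeError(f"LOOCV fold {i} failed: {err}") from err
        _, code = predict(model, X[i])
        predicted[i] = code[0]
    return ConfusionMatrix.from_codes(y, predicted), predicted
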