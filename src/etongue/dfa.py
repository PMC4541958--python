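"""Discriminant Factorial Analysis (multi-class canonical discriminant
analysis) with a distance classification rule and a Discrimination Index.

The discriminant axes solve the generalized eigenproblem

    S_b v = lambda * S_w v

where S_b and S_w are the between- and within-class scatter matrices of the
training features.  Because feature dimension can exceed the class-adjusted
degrees of freedom (64 FFT features vs 80 samples), S_w is
shrinkage-regularized with a small ridge, eps * trace(S_w)/p * I.

Per-axis eigenvalue share ("contribution") and canonical correlation
sqrt(lambda / (1 + lambda)) summarize each axis.  Samples are classified by
the distance rule — nearest class centroid in discriminant-score space over
all axes, ties toward the lowest class code.

The Discrimination Index (DI) condenses the 2-D discrimination map into an
integer 0..100: DI = round(100 * between-class sum of squares / total sum of
squares) computed on the first two axes.  DI = 100 exactly iff within-class
scatter vanishes in that plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

#: Ridge fraction applied to the within-class scatter.
RIDGE_EPS = 1e-6


class DegenerateScatterError(ValueError):
    """Feature scatter is identically zero; no discriminant axes exist."""


@dataclass
class DFAModel:
    """Fitted canonical discriminant axes and per-class geometry."""

    axes: np.ndarray  # (p, m) direction vectors, m = min(g - 1, p)
    eigenvalues: np.ndarray  # (m,), non-negative, descending
    contribution: np.ndarray  # (m,), eigenvalue shares summing to 1
    accumulated_contribution: np.ndarray  # (m,), cumulative shares
    canonical_correlations: np.ndarray  # (m,), in [0, 1]
    grand_mean: np.ndarray  # (p,)
    class_codes: np.ndarray  # (g,) sorted codes
    class_centroids: np.ndarray  # (g, m) centroid scores on all axes
    scores_2d: np.ndarray  # (n, 2) training scores on the first two axes


def fit_dfa(features: np.ndarray, labels: np.ndarray) -> DFAModel:
    """Fit canonical discriminant axes from labelled feature vectors.

    ``labels`` are integer class codes.  Every class needs at least two
    samples so the within-class scatter is estimable.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n, p) with one label per row")
    n, p = X.shape
    codes = np.unique(y)
    g = codes.size
    if g < 2:
        raise ValueError("need at least two classes")
    if n <= g:
        raise ValueError("need more samples than classes")

    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = np.empty((g, p))
    for i, c in enumerate(codes):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        mu = Xc.mean(axis=0)
        means[i] = mu
        d = Xc - mu
        Sw += d.T @ d
        dm = mu - grand
        Sb += Xc.shape[0] * np.outer(dm, dm)

    total_trace = np.trace(Sw) + np.trace(Sb)
    if total_trace == 0.0:
        raise DegenerateScatterError("all feature vectors are identical")
    ridge = RIDGE_EPS * (np.trace(Sw) + np.trace(Sb)) / p
    Sw_reg = Sw + ridge * np.eye(p)

    eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1]
    m = min(g - 1, p)
    eigvals = np.clip(eigvals[order][:m], 0.0, None)
    axes = eigvecs[:, order][:, :m]

    # sign convention: first loading of non-negligible magnitude is positive
    for j in range(m):
        col = axes[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12 * np.abs(col).max())
        if nz.size and col[nz[0]] < 0:
            axes[:, j] = -col

    total = eigvals.sum()
    contribution = eigvals / total if total > 0 else np.zeros(m)
    centroids = (means - grand) @ axes
    scores = (X - grand) @ axes
    return DFAModel(
        axes=axes,
        eigenvalues=eigvals,
        contribution=contribution,
        accumulated_contribution=np.cumsum(contribution),
        canonical_correlations=np.sqrt(eigvals / (1.0 + eigvals)),
        grand_mean=grand,
        class_codes=codes,
        class_centroids=centroids,
        scores_2d=scores[:, : min(2, m)],
    )


def project(model: DFAModel, features: np.ndarray) -> np.ndarray:
    """Scores of new samples on the first two discriminant axes."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.grand_mean.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension "
            f"{model.grand_mean.size}"
        )
    m2 = min(2, model.axes.shape[1])
    return (X - model.grand_mean) @ model.axes[:, :m2]


def classify_distance(model: DFAModel, features: np.ndarray) -> np.ndarray:
    """Distance rule: nearest class centroid in full discriminant space.

    Ties resolve to the lowest class code (centroids are stored in sorted
    code order and argmin returns the first minimum).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    scores = (X - model.grand_mean) @ model.axes
    d2 = ((scores[:, None, :] - model.class_centroids[None, :, :]) ** 2).sum(axis=2)
    return model.class_codes[np.argmin(d2, axis=1)]


def discrimination_index(
    model: DFAModel, features: np.ndarray, labels: np.ndarray
) -> int:
    """DI = round(100 x between-class SS / total SS) on the first two axes."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    s = project(model, X)
    center = s.mean(axis=0)
    tss = float(((s - center) ** 2).sum())
    if tss == 0.0:
        raise DegenerateScatterError("zero total scatter on the first two axes")
    bss = 0.0
    for c in np.unique(y):
        sc = s[y == c]
        bss += sc.shape[0] * float(((sc.mean(axis=0) - center) ** 2).sum())
    return int(np.floor(100.0 * bss / tss + 0.5))
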