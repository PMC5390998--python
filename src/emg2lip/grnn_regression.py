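"""Modified general regression neural network with anisotropic kernels.

A GRNN interpolates training targets with weights taken from a Parzen-style
density estimate around the probe.  Here the isotropic Gaussian kernel of
the textbook GRNN is replaced by a full multivariate normal likelihood per
training class (one class per (pose, repetition) pair in the pool, linear
index c = 12(r-1) + p, 48 classes for a 4-repetition pool):

    s(g, g_c) = N(g - g_c; 0, alpha^2 C_c + gamma I)

where g_c is the class's time-averaged 8D feature vector, C_c the sample
covariance of its feature time series, alpha >= 1 a kernel spread factor
that widens the sparsely populated classes, and gamma (default 1e-6) a
small stabiliser.  The pose estimate is the similarity-weighted convex
combination of the training lip poses, X_hat = sum_c w_c X_c, with the
weights normalised over all classes in the pool.

The full normalising constant of each Gaussian is retained: covariances
differ per class, so the determinants genuinely reweight the classes.
Weights are evaluated in log space (max-subtraction before exponentiation)
to survive underflow in 8 dimensions; when even the best class underflows
a direct density evaluation, the estimate falls back to the single most
likely class with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as _linalg

__all__ = [
    "GRNNModel",
    "KernelWeights",
    "CovarianceError",
    "ALPHA_GRID",
    "fit_grnn",
    "log_similarities",
    "similarity",
    "predict_pose",
]

#: Kernel spread factors swept during cross-validated model selection.
ALPHA_GRID: tuple[int, ...] = tuple(range(1, 11))

_N_FEAT = 8


class CovarianceError(ValueError):
    """Class covariance not estimable or effective kernel not PD."""


@dataclass
class GRNNModel:
    """Per-class Gaussian likelihood models and associated lip poses."""

    mu: np.ndarray  # n_classes x 8 class means (time-averaged features)
    cov: np.ndarray  # n_classes x 8 x 8 sample covariances
    X: np.ndarray  # n_classes x 30 lip poses
    alpha: float = 2.0
    gamma: float = 1e-6

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.mu.shape[0]
        if self.mu.shape != (n, _N_FEAT) or self.cov.shape != (n, _N_FEAT, _N_FEAT):
            raise ValueError("mu must be (n, 8) and cov (n, 8, 8)")
        if self.X.shape[0] != n:
            raise ValueError("one lip pose per class required")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        self._prepare_kernels()

    @property
    def n_classes(self) -> int:
        return self.mu.shape[0]

    def _prepare_kernels(self) -> None:
        """Cholesky factors and log-determinants of alpha^2 C_c + gamma I."""
        self._chol = []
        self._logdet = np.empty(self.n_classes)
        eye = np.eye(_N_FEAT)
        for c in range(self.n_classes):
            S = self.alpha**2 * self.cov[c] + self.gamma * eye
            try:
                L = _linalg.cholesky(S, lower=True)
            except _linalg.LinAlgError as exc:
                raise CovarianceError(
                    f"effective covariance of class {c} not positive definite; "
                    "increase gamma"
                ) from exc
            self._chol.append(L)
            self._logdet[c] = 2.0 * np.sum(np.log(np.diag(L)))


@dataclass
class KernelWeights:
    """Similarity-normalised weights on the probability simplex."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0) or not np.isclose(self.w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to one")


def fit_grnn(
    feature_sets: np.ndarray,
    poses: np.ndarray,
    alpha: float = 2.0,
    gamma: float = 1e-6,
) -> GRNNModel:
    """Fit per-class means and covariances from feature time series.

    ``feature_sets`` is (n_classes, T, 8) — one feature series g(i, p, r)
    per training record (nominally T = 6145) — and ``poses`` the matching
    (n_classes, 30) lip vectors.  Means are time averages; covariances are
    sample covariances over the time samples (1/(T-1) normalisation).
    """
    series = [np.asarray(s, dtype=float) for s in feature_sets]
    poses = np.asarray(poses, dtype=float)
    if len(series) != poses.shape[0]:
        raise ValueError("one pose per feature set required")
    mu = np.empty((len(series), _N_FEAT))
    cov = np.empty((len(series), _N_FEAT, _N_FEAT))
    for c, s in enumerate(series):
        if s.ndim != 2 or s.shape[1] != _N_FEAT:
            raise ValueError("each feature set must be (T, 8)")
        if s.shape[0] < 2:
            raise CovarianceError(
                "at least 2 time samples per class required for a covariance"
            )
        mu[c] = s.mean(axis=0)
        cov[c] = np.cov(s, rowvar=False, ddof=1)
    return GRNNModel(mu=mu, cov=cov, X=poses, alpha=alpha, gamma=gamma)


def log_similarities(gbar: np.ndarray, model: GRNNModel) -> np.ndarray:
    """Log of the similarity s(g, g_c) for every class (full normal
    log-density, normalising constant included)."""
    g = np.asarray(gbar, dtype=float)
    if g.shape != (_N_FEAT,):
        raise ValueError("probe must be an 8-element feature vector")
    out = np.empty(model.n_classes)
    const = _N_FEAT * np.log(2.0 * np.pi)
    for c in range(model.n_classes):
        d = _linalg.solve_triangular(model._chol[c], g - model.mu[c], lower=True)
        out[c] = -0.5 * (const + model._logdet[c] + d @ d)
    return out


def similarity(gbar: np.ndarray, c: int, model: GRNNModel) -> float:
    """Similarity of the probe to class ``c`` (a normal density value)."""
    return float(np.exp(log_similarities(gbar, model)[c]))


def predict_pose(
    gbar: np.ndarray, model: GRNNModel
) -> tuple[np.ndarray, KernelWeights]:
    """Kernel-weighted lip-pose estimate X_hat = sum_c w_c X_c.

    Weights are the class similarities normalised to sum to one, computed
    in log space.  If the probe is so far from every class that all direct
    densities underflow, the estimate collapses (with a warning) to the
    class with the largest log-density.
    """
    logs = log_similarities(gbar, model)
    top = logs.max()
    if top < np.log(np.finfo(float).tiny):
        warnings.warn(
            "probe outside the populated feature region: all similarities "
            "underflow; falling back to the most likely class"
        )
        w = np.zeros_like(logs)
        w[int(np.argmax(logs))] = 1.0
    else:
        w = np.exp(logs - top)
        w /= w.sum()
    weights = KernelWeights(w=w)
    return model.X.T @ w, weights
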