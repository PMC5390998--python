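"""Joint position-feature PCA regression with LSE/MMSE coefficient estimation.

Each training record couples a 30-coordinate lip-marker vector X(p, r) with
a 44-element quadratically augmented sEMG feature vector into a 74D joint
vector z.  After per-element normalisation (zero mean, unit variance over
the training pool), the principal subspace Y (74 x D, orthonormal columns)
of the pooled training matrix captures the joint covariation of shape and
muscle activity.  At test time only the feature block is observed; the PCA
coefficients b are recovered from the lower 44 rows Y_g of Y either by
least squares,

    b_LSE = (Y_g^T Y_g)^{-1} Y_g^T g,

or by the unbiased MMSE estimator that shrinks towards the zero-mean prior
with per-coefficient variances lambda_d and residual noise scale sigma_v,

    b_MMSE = (Y_g^T Y_g + sigma_v^2 C_b^{-1})^{-1} Y_g^T g,  C_b = diag(lambda).

For C_b to be the prior covariance of the coefficients — which is what
makes the shrinkage statistically meaningful — the lambda_d are the
eigenvalues of the training *covariance* matrix (the squared singular
values of the normalised pool divided by n - 1).  With sigma_v = 0 the
two estimators coincide.  Decoding z = Y b and undoing the normalisation
yields the estimated 30 lip coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_POSITION",
    "N_FEATURE",
    "N_JOINT",
    "PCAModel",
    "CoefficientVector",
    "RegularisationError",
    "build_joint_matrix",
    "normalise",
    "denormalise",
    "fit_pca",
    "encode",
    "decode",
    "estimate_lse",
    "estimate_mmse",
    "predict_pose",
    "explained_variance",
]

N_POSITION = 30  # 10 lip markers x 3 coordinates
N_FEATURE = 44  # 8 linear + 36 quadratic feature terms
N_JOINT = N_POSITION + N_FEATURE

#: Parameter grids swept during cross-validated model selection.
SIGMA_V_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.3001, 0.05), 2))
D_GRID: tuple[int, ...] = tuple(range(1, 49))


class RegularisationError(ValueError):
    """MMSE shrinkage requested with a non-positive prior eigenvalue."""


@dataclass
class PCAModel:
    """Normalisation statistics plus the sorted principal subspace."""

    mean: np.ndarray  # 74 per-element training means
    var: np.ndarray  # 74 per-element training sample variances (guarded > 0)
    Y: np.ndarray  # 74 x D orthonormal eigenvector matrix, sorted
    lambdas: np.ndarray  # D non-increasing eigenvalues
    sigma_v: float = 0.0
    all_lambdas: np.ndarray | None = None  # full spectrum, for variance reports

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.mean.shape != (N_JOINT,) or self.var.shape != (N_JOINT,):
            raise ValueError(f"normalisation statistics must have {N_JOINT} elements")
        if self.Y.shape[0] != N_JOINT or self.Y.shape[1] != self.lambdas.size:
            raise ValueError("Y must be 74 x D with one eigenvalue per column")
        if np.any(np.diff(self.lambdas) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def D(self) -> int:
        return self.Y.shape[1]

    @property
    def Y_x(self) -> np.ndarray:
        """Upper 30 rows of Y (position block)."""
        return self.Y[:N_POSITION]

    @property
    def Y_g(self) -> np.ndarray:
        """Lower 44 rows of Y (feature block)."""
        return self.Y[N_POSITION:]


@dataclass
class CoefficientVector:
    b: np.ndarray
    estimator: str  # {"encode", "LSE", "MMSE"}

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)


def build_joint_matrix(X: np.ndarray, gbar_aug: np.ndarray) -> np.ndarray:
    """Stack position (30) over feature (44) blocks into a 74 x n matrix.

    ``X`` is (n, 30) and ``gbar_aug`` is (n, 44); records become columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = np.atleast_2d(np.asarray(gbar_aug, dtype=float))
    if X.shape[1] != N_POSITION or G.shape[1] != N_FEATURE or X.shape[0] != G.shape[0]:
        raise ValueError("expected matching (n, 30) positions and (n, 44) features")
    return np.vstack([X.T, G.T])


def normalise(vectors: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Shift/scale elements (first axis) with training statistics."""
    v = np.asarray(vectors, dtype=float)
    shift = mean[:, None] if v.ndim == 2 else mean
    return (v - shift) / _as_scale(var, v.ndim)


def denormalise(vectors: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalise`."""
    v = np.asarray(vectors, dtype=float) * _as_scale(var, np.ndim(vectors))
    return v + (mean[:, None] if v.ndim == 2 else mean)


def _as_scale(var: np.ndarray, ndim: int) -> np.ndarray:
    s = np.sqrt(var)
    return s[:, None] if ndim == 2 else s


def _guard_variance(var: np.ndarray) -> np.ndarray:
    bad = var <= np.finfo(float).tiny
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} zero-variance element(s) guarded during normalisation"
        )
        var = var.copy()
        var[bad] = 1.0
    return var


def fit_pca(
    Z_train: np.ndarray,
    D: int | None = None,
    sigma_v: float = 0.0,
) -> PCAModel:
    """Fit normalisation statistics and the principal subspace of Z_train.

    ``Z_train`` is 74 x n with one joint vector per column (n = 48 in a
    full cross-validation fold: 12 poses x 4 repetitions, rest excluded).
    The eigenproblem of Z Z^T is solved through the thin SVD of the
    normalised matrix, which never forms the 74 x 74 outer product.  A
    request for more components than the matrix rank triggers a rank
    warning and the retained spectrum is padded with zero eigenvalues.

    Sign convention: the largest-magnitude element of each eigenvector is
    made positive.  Eigenvalue ties keep the solver's original order.
    """
    Z = np.asarray(Z_train, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != N_JOINT:
        raise ValueError(f"Z_train must be {N_JOINT} x n")
    n = Z.shape[1]
    mean = Z.mean(axis=1)
    var = _guard_variance(Z.var(axis=1, ddof=1))
    Zn = normalise(Z, mean, var)

    U, s, _ = np.linalg.svd(Zn, full_matrices=False)
    # eigenvalues of the training *covariance* (1/(n-1) normalisation), so
    # that diag(lambda) genuinely is the prior coefficient covariance C_b
    # used by the MMSE shrinkage
    lambdas = s**2 / max(n - 1, 1)
    rank = int(np.sum(s > s[0] * max(Z.shape) * np.finfo(float).eps)) if s.size else 0
    if D is None:
        D = min(n, N_JOINT)
    if D > rank:
        warnings.warn(
            f"requested D={D} exceeds the numerical rank {rank} of the training pool"
        )
    D = min(D, U.shape[1])
    Y = U[:, :D].copy()
    lam = lambdas[:D].copy()
    lam[rank:] = 0.0
    # make the largest-magnitude element of each component positive
    flip = np.sign(Y[np.abs(Y).argmax(axis=0), np.arange(D)])
    flip[flip == 0] = 1.0
    Y *= flip
    return PCAModel(
        mean=mean, var=var, Y=Y, lambdas=lam, sigma_v=sigma_v, all_lambdas=lambdas
    )


def explained_variance(model: PCAModel, D: int | None = None) -> float:
    """Fraction of total training variance captured by the leading D
    components (uses the full spectrum recorded at fit time)."""
    lam = model.all_lambdas if model.all_lambdas is not None else model.lambdas
    D = model.D if D is None else D
    total = lam.sum()
    return float(lam[:D].sum() / total) if total > 0 else 0.0


def encode(z: np.ndarray, model: PCAModel) -> CoefficientVector:
    """b = Y^T z for a normalised 74-vector z."""
    z = np.asarray(z, dtype=float)
    if z.shape != (N_JOINT,):
        raise ValueError(f"expected a {N_JOINT}-element normalised vector")
    return CoefficientVector(b=model.Y.T @ z, estimator="encode")


def decode(b: CoefficientVector | np.ndarray, model: PCAModel) -> np.ndarray:
    """z ~ Y b (still normalised)."""
    bb = b.b if isinstance(b, CoefficientVector) else np.asarray(b, dtype=float)
    if bb.shape != (model.D,):
        raise ValueError(f"coefficient vector must have D={model.D} elements")
    return model.Y @ bb


def _normalise_features(gbar_aug: np.ndarray, model: PCAModel) -> np.ndarray:
    g = np.asarray(gbar_aug, dtype=float)
    if g.shape != (N_FEATURE,):
        raise ValueError(f"expected a {N_FEATURE}-element augmented feature vector")
    return (g - model.mean[N_POSITION:]) / np.sqrt(model.var[N_POSITION:])


def _solve_normal(A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve the (regularised) normal equations; fall back to the
    pseudo-inverse with a warning when the system is singular."""
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("singular normal matrix; using pseudo-inverse solution")
        return np.linalg.pinv(A) @ rhs
    return np.linalg.solve(A, rhs)


def estimate_lse(gbar_aug: np.ndarray, model: PCAModel) -> CoefficientVector:
    """Least-squares coefficients from the feature block alone."""
    gn = _normalise_features(gbar_aug, model)
    Yg = model.Y_g
    b = _solve_normal(Yg.T @ Yg, Yg.T @ gn)
    return CoefficientVector(b=b, estimator="LSE")


def estimate_mmse(
    gbar_aug: np.ndarray, model: PCAModel, sigma_v: float | None = None
) -> CoefficientVector:
    """MMSE coefficients shrinking towards the PCA prior.

    With ``sigma_v = 0`` the regulariser vanishes and the estimate equals
    the LSE solution.
    """
    sv = model.sigma_v if sigma_v is None else sigma_v
    if sv < 0:
        raise ValueError("sigma_v must be non-negative")
    if sv > 0 and np.any(model.lambdas <= 0):
        raise RegularisationError(
            "MMSE with sigma_v > 0 requires strictly positive eigenvalues; "
            "reduce D to the training-pool rank"
        )
    gn = _normalise_features(gbar_aug, model)
    Yg = model.Y_g
    A = Yg.T @ Yg
    if sv > 0:
        A = A + sv**2 * np.diag(1.0 / model.lambdas)
    b = _solve_normal(A, Yg.T @ gn)
    return CoefficientVector(b=b, estimator="MMSE")


def predict_pose(
    gbar_aug: np.ndarray,
    model: PCAModel,
    estimator: str = "MMSE",
    sigma_v: float | None = None,
) -> np.ndarray:
    """Estimate the 30 lip coordinates X(p, r) from raw augmented features.

    Features are normalised with the *training* statistics, coefficients
    estimated (LSE or MMSE), the full joint vector decoded, and the
    normalisation undone; the position block is returned in mm.
    """
    if estimator.upper() == "LSE":
        coeff = estimate_lse(gbar_aug, model)
    elif estimator.upper() == "MMSE":
        coeff = estimate_mmse(gbar_aug, model, sigma_v=sigma_v)
    else:
        raise ValueError("estimator must be 'LSE' or 'MMSE'")
    z_hat = decode(coeff, model)
    z_hat = denormalise(z_hat, model.mean, model.var)
    return z_hat[:N_POSITION]
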