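"""Corrected error metrics, cross-validation, and settings grid search.

The study design behind these metrics: five repetitions of twelve active
poses plus a rest pose, ten lip markers (30 coordinates) per pose, with
marker positions obtained by manual selection in stereo images.  Manual
selection is itself noisy, so raw RMS errors are corrected for the
intraobserver error e_obs measured from two independent selection runs:

* e_obs   - RMS Euclidean difference between two selection runs over the
            ten markers and thirteen poses (rest included).
* d_RMS   - RMS displacement of the active poses from the repetition's
            rest pose, averaged over 12 poses x 5 repetitions; corrected
            magnitude d_c = sqrt(d_RMS^2 - e_obs^2) (both selections noisy).
* e_RMS   - RMS difference between estimated and selected marker
            positions; corrected error e_c = sqrt(e_RMS^2 - e_obs^2 / 2)
            (only one selection run enters the comparison).
* e_r     - e_c / d_c, the error relative to how much the lips moved.
* rho     - mean of the 30 per-coordinate Pearson correlations between
            estimated and selected positions over the 60 records.

Model selection follows the leave-one-repetition-out protocol: each of the
five repetitions is held out once (48 training / 12 test records per fold),
squared residuals are pooled over all folds before the RMS, and the
corrected error is averaged over volunteers to pick volunteer-independent
settings from the 2 configurations x 5 features x 6 windows grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from . import grnn_regression as _grnn
from . import pca_regression as _pca

__all__ = [
    "FeatureSetting",
    "VolunteerDataset",
    "ErrorReport",
    "GridResult",
    "GridSearchResult",
    "EvaluationDomainError",
    "IncompleteDesignError",
    "feature_settings_grid",
    "intraobserver_error",
    "corrected_deviation",
    "corrected_error",
    "deviation_metrics",
    "estimation_error",
    "underestimation_factor",
    "correlation_summary",
    "loo_cv",
    "pca_param_sweep",
    "grnn_param_sweep",
    "grid_search",
    "paired_ttest",
]

N_POSES_ACTIVE = 12
N_REPETITIONS = 5
N_MARKERS = 10


class EvaluationDomainError(ValueError):
    """Error correction undefined (corrected squared error negative)."""


class IncompleteDesignError(ValueError):
    """Dataset does not cover the full 12 poses x 5 repetitions design."""


# Feature ordering follows the study's numbering: 1 WAMP(10), 2 WAMP(20),
# 3 WL, 4 MAV, 5 RMS; unipolar precedes bipolar.  Used for deterministic
# tie-breaking only.
_FEATURE_ORDER = (("WAMP", 10.0), ("WAMP", 20.0), ("WL", None), ("MAV", None), ("RMS", None))
_CONFIG_ORDER = ("unipolar", "bipolar")


@dataclass(frozen=True)
class FeatureSetting:
    """One cell of the configuration x feature x window settings grid."""

    configuration: str
    feature_type: str
    window_ms: float
    s_lim: float | None = None

    @property
    def label(self) -> str:
        feat = self.feature_type
        if self.s_lim is not None:
            feat += f"{self.s_lim:g}"
        return f"{self.configuration}/{feat}/{self.window_ms:g}ms"

    def _tie_key(self) -> tuple:
        feat_rank = _FEATURE_ORDER.index((self.feature_type, self.s_lim))
        return (self.window_ms, _CONFIG_ORDER.index(self.configuration), feat_rank)


def feature_settings_grid(
    configurations: tuple[str, ...] = _CONFIG_ORDER,
    windows_ms: tuple[float, ...] = (50, 100, 150, 200, 250, 300),
) -> list[FeatureSetting]:
    """Enumerate the settings grid (2 x 5 x 6 = 60 cells by default)."""
    return [
        FeatureSetting(conf, feat, win, s_lim)
        for conf in configurations
        for feat, s_lim in _FEATURE_ORDER
        for win in windows_ms
    ]


@dataclass
class VolunteerDataset:
    """Complete per-volunteer design at one feature/window setting.

    Axis conventions: pose index p-1 (active poses 1..12), repetition
    index r-1 (repetitions 1..5).
    """

    X: np.ndarray  # (12, 5, 30) registered lip coordinates, mm
    rest: np.ndarray  # (5, 30) rest-pose coordinates per repetition
    gbar: np.ndarray  # (12, 5, 8) averaged feature vectors
    gbar_aug: np.ndarray  # (12, 5, 44) augmented feature vectors
    e_obs: float  # intraobserver error, mm
    series: np.ndarray | None = None  # (12, 5, T, 8) feature series (GRNN)
    volunteer_id: int = 0
    setting: FeatureSetting | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.rest = np.asarray(self.rest, dtype=float)
        self.gbar = np.asarray(self.gbar, dtype=float)
        self.gbar_aug = np.asarray(self.gbar_aug, dtype=float)
        expect = {
            "X": (N_POSES_ACTIVE, N_REPETITIONS, 30),
            "rest": (N_REPETITIONS, 30),
            "gbar": (N_POSES_ACTIVE, N_REPETITIONS, 8),
            "gbar_aug": (N_POSES_ACTIVE, N_REPETITIONS, 44),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise IncompleteDesignError(f"{name} must have shape {shape}")
            if not np.all(np.isfinite(arr)):
                raise IncompleteDesignError(f"{name} contains missing values")

    def joint_matrix(self, repetitions: np.ndarray) -> np.ndarray:
        """74 x (12 * len(repetitions)) training matrix; columns ordered by
        the linear class index c = 12 (r - 1) + p."""
        X = self.X[:, repetitions].transpose(1, 0, 2).reshape(-1, 30)
        G = self.gbar_aug[:, repetitions].transpose(1, 0, 2).reshape(-1, 44)
        return _pca.build_joint_matrix(X, G)


@dataclass
class ErrorReport:
    """Raw and corrected error summary of one cross-validated run."""

    e_obs: float
    d_rms: float
    d_c: float
    e_rms: float
    e_c: float
    e_r: float
    rho: float
    rho_per_coordinate: np.ndarray | None = None
    n_excluded_coordinates: int = 0
    method: str = ""
    params: dict = field(default_factory=dict)


@dataclass
class GridResult:
    """One evaluated cell of the full settings/parameter grid."""

    setting: FeatureSetting
    params: dict  # {"D": .., "sigma_v": ..} or {"alpha": ..}
    e_c_per_volunteer: dict[int, float]
    e_c_average: float

    def _tie_key(self) -> tuple:
        param = self.params.get("D", self.params.get("alpha", 0))
        sigma = self.params.get("sigma_v", 0.0)
        win, conf, feat = self.setting._tie_key()
        return (self.e_c_average, win, param, sigma, conf, feat)


@dataclass
class GridSearchResult:
    results: list[GridResult]
    best: GridResult  # volunteer-independent optimum
    best_per_volunteer: dict[int, GridResult]


def _rms_per_marker(diff: np.ndarray) -> float:
    """RMS Euclidean length per marker: sqrt(sum of squared coordinate
    differences / (n_records * n_markers)).  With 12 poses x 5 repetitions
    this is the study's 1/600 normaliser."""
    diff = np.asarray(diff, dtype=float)
    n_records = diff.size // 30
    return float(np.sqrt(np.sum(diff**2) / (n_records * N_MARKERS)))


def intraobserver_error(sel1: np.ndarray, sel2: np.ndarray) -> float:
    """RMS discrepancy between two manual selection runs (mm).

    ``sel1``/``sel2`` are (13, 30) marker-coordinate arrays covering the
    rest pose and the twelve active poses of one repetition.
    """
    a = np.asarray(sel1, dtype=float)
    b = np.asarray(sel2, dtype=float)
    if a.shape != b.shape or a.shape[-1] != 30:
        raise ValueError("selection runs must be matching (n_poses, 30) arrays")
    return _rms_per_marker(a - b)


def corrected_deviation(d_rms: float, e_obs: float) -> float:
    """d_c = sqrt(d_RMS^2 - e_obs^2); both selections carry observer noise."""
    val = d_rms**2 - e_obs**2
    if -1e-9 * max(e_obs**2, 1e-300) <= val < 0:  # exact boundary, roundoff
        val = 0.0
    if val < 0:
        raise EvaluationDomainError(
            f"d_RMS ({d_rms:.3f}) below the intraobserver error ({e_obs:.3f}); "
            "corrected deviation undefined"
        )
    return float(np.sqrt(val))


def corrected_error(e_rms: float, e_obs: float) -> float:
    """e_c = sqrt(e_RMS^2 - e_obs^2 / 2); a single selection run enters."""
    val = e_rms**2 - 0.5 * e_obs**2
    if -1e-9 * max(e_obs**2, 1e-300) <= val < 0:  # exact boundary, roundoff
        val = 0.0
    if val < 0:
        raise EvaluationDomainError(
            f"e_RMS ({e_rms:.3f}) below e_obs/sqrt(2) ({e_obs / np.sqrt(2):.3f}); "
            "corrected error undefined"
        )
    return float(np.sqrt(val))


def deviation_metrics(
    poses: np.ndarray, rest_poses: np.ndarray, e_obs: float
) -> tuple[float, float]:
    """(d_RMS, d_c): magnitude of marker displacement from rest.

    ``poses`` is (12, 5, 30) and ``rest_poses`` (5, 30); each record is
    compared against the rest pose of its own repetition.
    """
    poses = np.asarray(poses, dtype=float)
    rest = np.asarray(rest_poses, dtype=float)
    d_rms = _rms_per_marker(poses - rest[None, :, :])
    return d_rms, corrected_deviation(d_rms, e_obs)


def estimation_error(
    estimates: np.ndarray,
    truths: np.ndarray,
    e_obs: float,
    d_c: float | None = None,
) -> tuple[float, float, float | None]:
    """(e_RMS, e_c, e_r): accuracy of estimated marker positions.

    ``estimates`` and ``truths`` are matching (..., 30) arrays covering the
    12 x 5 design.  ``e_r = e_c / d_c`` is returned when ``d_c`` is given.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have matching shapes")
    e_rms = _rms_per_marker(est - tru)
    e_c = corrected_error(e_rms, e_obs)
    e_r = e_c / d_c if d_c is not None else None
    return e_rms, e_c, e_r


def underestimation_factor(e_obs: float, e_meas: float) -> float:
    """sqrt(e_obs^2 / (e_meas^2 + e_obs^2)): how much the total error is
    underestimated when the measurement-device error is neglected."""
    if e_obs < 0 or e_meas < 0:
        raise ValueError("errors must be non-negative")
    denom = e_meas**2 + e_obs**2
    if denom == 0:
        raise EvaluationDomainError("both error terms are zero")
    return float(np.sqrt(e_obs**2 / denom))


def correlation_summary(
    estimates: np.ndarray, truths: np.ndarray
) -> tuple[np.ndarray, float, int]:
    """Per-coordinate Pearson correlations and their mean.

    Correlations are computed across the pooled (pose, repetition) records
    for each of the 30 coordinates.  Zero-variance coordinates (Pearson
    undefined) are excluded from the mean with a warning; the per-
    coordinate array carries NaN there.  Returns (coefficients, mean,
    number excluded).
    """
    est = np.asarray(estimates, dtype=float).reshape(-1, 30)
    tru = np.asarray(truths, dtype=float).reshape(-1, 30)
    if est.shape != tru.shape or est.shape[0] < 2:
        raise ValueError("need matching arrays with at least 2 records")
    coeffs = np.full(30, np.nan)
    for m in range(30):
        if np.ptp(est[:, m]) == 0 or np.ptp(tru[:, m]) == 0:
            continue
        coeffs[m] = _stats.pearsonr(est[:, m], tru[:, m]).statistic
    n_excluded = int(np.isnan(coeffs).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} zero-variance coordinate(s) excluded from rho"
        )
    rho = float(np.nanmean(coeffs))
    return coeffs, rho, n_excluded


def _cv_estimates_pca(
    data: VolunteerDataset, D: int, sigma_v: float, estimator: str
) -> np.ndarray:
    estimates = np.empty_like(data.X)
    for r_test in range(N_REPETITIONS):
        train = np.array([r for r in range(N_REPETITIONS) if r != r_test])
        model = _pca.fit_pca(data.joint_matrix(train), D=D, sigma_v=sigma_v)
        for p in range(N_POSES_ACTIVE):
            estimates[p, r_test] = _pca.predict_pose(
                data.gbar_aug[p, r_test], model, estimator=estimator
            )
    return estimates


def _cv_estimates_grnn(
    data: VolunteerDataset, alpha: float, gamma: float
) -> np.ndarray:
    if data.series is None:
        raise IncompleteDesignError(
            "GRNN cross-validation needs the per-record feature series"
        )
    estimates = np.empty_like(data.X)
    for r_test in range(N_REPETITIONS):
        train = [r for r in range(N_REPETITIONS) if r != r_test]
        series = [data.series[p, r] for r in train for p in range(N_POSES_ACTIVE)]
        poses = np.array([data.X[p, r] for r in train for p in range(N_POSES_ACTIVE)])
        model = _grnn.fit_grnn(series, poses, alpha=alpha, gamma=gamma)
        for p in range(N_POSES_ACTIVE):
            estimates[p, r_test], _ = _grnn.predict_pose(data.gbar[p, r_test], model)
    return estimates


def loo_cv(
    data: VolunteerDataset,
    method: str = "pca",
    *,
    estimator: str = "MMSE",
    D: int = 9,
    sigma_v: float = 0.05,
    alpha: float = 2.0,
    gamma: float = 1e-6,
    return_estimates: bool = False,
):
    """Leave-one-repetition-out cross-validation of one method/setting.

    Five folds: each repetition is the test set exactly once (74 x 48
    training matrix, 74 x 12 test matrix per fold for the PCA route).
    Squared residuals are pooled across all folds before the RMS.
    """
    if method == "pca":
        estimates = _cv_estimates_pca(data, D, sigma_v, estimator)
        params = {"D": D, "sigma_v": sigma_v, "estimator": estimator}
    elif method == "grnn":
        estimates = _cv_estimates_grnn(data, alpha, gamma)
        params = {"alpha": alpha, "gamma": gamma}
    else:
        raise ValueError("method must be 'pca' or 'grnn'")
    d_rms, d_c = deviation_metrics(data.X, data.rest, data.e_obs)
    e_rms, e_c, e_r = estimation_error(estimates, data.X, data.e_obs, d_c)
    coeffs, rho, n_excl = correlation_summary(estimates, data.X)
    report = ErrorReport(
        e_obs=data.e_obs,
        d_rms=d_rms,
        d_c=d_c,
        e_rms=e_rms,
        e_c=e_c,
        e_r=e_r,
        rho=rho,
        rho_per_coordinate=coeffs,
        n_excluded_coordinates=n_excl,
        method=method,
        params=params,
    )
    return (report, estimates) if return_estimates else report


def pca_param_sweep(
    data: VolunteerDataset,
    Ds: tuple[int, ...] = _pca.D_GRID,
    sigma_vs: tuple[float, ...] = _pca.SIGMA_V_GRID,
) -> np.ndarray:
    """Corrected error e_c for every (D, sigma_v) combination.

    One SVD per fold serves the whole grid: the D-dimensional model uses
    the leading D columns.  For D beyond the training-pool rank the MMSE
    prior variance of the extra coefficients is zero, which pins them to
    zero; that limit is realised by clipping D at the rank (for sigma_v = 0
    the pseudo-inverse least-squares solution is used instead).  Returns a
    (len(Ds), len(sigma_vs)) array; combinations whose corrected error is
    undefined come back as NaN.
    """
    sq_sums = np.zeros((len(Ds), len(sigma_vs)))
    for r_test in range(N_REPETITIONS):
        train = np.array([r for r in range(N_REPETITIONS) if r != r_test])
        model = _pca.fit_pca(data.joint_matrix(train), D=None)
        lam = model.lambdas
        rank = int(np.sum(lam > lam[0] * 1e-12)) if lam.size else 0
        G_test = np.stack(
            [
                _pca._normalise_features(data.gbar_aug[p, r_test], model)
                for p in range(N_POSES_ACTIVE)
            ],
            axis=1,
        )  # 44 x 12
        X_test = data.X[:, r_test]  # 12 x 30
        for i, D in enumerate(Ds):
            Deff = min(D, rank)
            Yg = model.Y[_pca.N_POSITION:, :Deff]
            Yx = model.Y[: _pca.N_POSITION, :Deff]
            A0 = Yg.T @ Yg
            rhs = Yg.T @ G_test  # Deff x 12
            for j, sv in enumerate(sigma_vs):
                if sv > 0:
                    A = A0 + sv**2 * np.diag(1.0 / lam[:Deff])
                    B = np.linalg.solve(A, rhs)
                else:
                    B = _pca._solve_normal(A0, rhs)
                Xn_hat = Yx @ B  # 30 x 12, still normalised
                X_hat = _pca.denormalise(
                    Xn_hat,
                    model.mean[: _pca.N_POSITION],
                    model.var[: _pca.N_POSITION],
                )
                sq_sums[i, j] += np.sum((X_hat.T - X_test) ** 2)
    e_rms = np.sqrt(sq_sums / (N_POSES_ACTIVE * N_REPETITIONS * N_MARKERS))
    with np.errstate(invalid="ignore"):
        e_c = np.sqrt(e_rms**2 - 0.5 * data.e_obs**2)
    return e_c


def grnn_param_sweep(
    data: VolunteerDataset,
    alphas: tuple[float, ...] = _grnn.ALPHA_GRID,
    gamma: float = 1e-6,
) -> np.ndarray:
    """Corrected error e_c for every kernel spread alpha (NaN where the
    correction is undefined)."""
    if data.series is None:
        raise IncompleteDesignError(
            "GRNN sweep needs the per-record feature series"
        )
    sq_sums = np.zeros(len(alphas))
    for r_test in range(N_REPETITIONS):
        train = [r for r in range(N_REPETITIONS) if r != r_test]
        series = [data.series[p, r] for r in train for p in range(N_POSES_ACTIVE)]
        poses = np.array([data.X[p, r] for r in train for p in range(N_POSES_ACTIVE)])
        for i, alpha in enumerate(alphas):
            model = _grnn.fit_grnn(series, poses, alpha=alpha, gamma=gamma)
            for p in range(N_POSES_ACTIVE):
                x_hat, _ = _grnn.predict_pose(data.gbar[p, r_test], model)
                sq_sums[i] += np.sum((x_hat - data.X[p, r_test]) ** 2)
    e_rms = np.sqrt(sq_sums / (N_POSES_ACTIVE * N_REPETITIONS * N_MARKERS))
    with np.errstate(invalid="ignore"):
        return np.sqrt(e_rms**2 - 0.5 * data.e_obs**2)


def grid_search(
    datasets: dict[int, dict[FeatureSetting, VolunteerDataset]],
    method: str = "pca",
    *,
    Ds: tuple[int, ...] = _pca.D_GRID,
    sigma_vs: tuple[float, ...] = _pca.SIGMA_V_GRID,
    alphas: tuple[float, ...] = _grnn.ALPHA_GRID,
    gamma: float = 1e-6,
) -> GridSearchResult:
    """Exhaustive settings/parameter grid search averaged over volunteers.

    ``datasets`` maps volunteer id -> feature setting -> dataset; every
    volunteer must cover the same settings.  For each setting and each
    method parameter combination the leave-one-repetition-out corrected
    error is computed per volunteer and averaged; the volunteer-independent
    optimum is the argmin of the average (ties broken deterministically by
    smaller window, smaller D/alpha, smaller sigma_v, unipolar first).
    Volunteers whose folds fail for a combination are excluded from that
    average with a warning.
    """
    volunteers = sorted(datasets)
    settings = sorted(datasets[volunteers[0]], key=FeatureSetting._tie_key)
    for vol in volunteers:
        if sorted(datasets[vol], key=FeatureSetting._tie_key) != settings:
            raise IncompleteDesignError("volunteers cover different settings grids")

    if method == "pca":
        param_list = [
            {"D": D, "sigma_v": sv} for D in Ds for sv in sigma_vs
        ]
    elif method == "grnn":
        param_list = [{"alpha": a, "gamma": gamma} for a in alphas]
    else:
        raise ValueError("method must be 'pca' or 'grnn'")

    results: list[GridResult] = []
    for setting in settings:
        per_vol: dict[int, np.ndarray] = {}
        for vol in volunteers:
            data = datasets[vol][setting]
            try:
                if method == "pca":
                    per_vol[vol] = pca_param_sweep(data, Ds, sigma_vs).ravel()
                else:
                    per_vol[vol] = grnn_param_sweep(data, alphas, gamma)
            except (EvaluationDomainError, IncompleteDesignError) as exc:
                warnings.warn(
                    f"volunteer {vol} excluded at {setting.label}: {exc}"
                )
        for k, params in enumerate(param_list):
            cell = {vol: float(arr[k]) for vol, arr in per_vol.items()}
            valid = [v for v in cell.values() if np.isfinite(v)]
            avg = float(np.mean(valid)) if valid else np.nan
            results.append(GridResult(setting, params, cell, avg))

    finite = [r for r in results if np.isfinite(r.e_c_average)]
    if not finite:
        raise EvaluationDomainError("no grid cell produced a finite error")
    best = min(finite, key=GridResult._tie_key)
    best_per_volunteer: dict[int, GridResult] = {}
    for vol in volunteers:
        candidates = [
            r for r in results if np.isfinite(r.e_c_per_volunteer.get(vol, np.nan))
        ]
        best_per_volunteer[vol] = min(
            candidates,
            key=lambda r: (r.e_c_per_volunteer[vol],) + r._tie_key()[1:],
        )
    return GridSearchResult(results, best, best_per_volunteer)


def paired_ttest(a, b, alternative: str = "two-sided"):
    """Thin convenience wrapper around the paired Student t-test."""
    return _stats.ttest_rel(a, b, alternative=alternative)
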