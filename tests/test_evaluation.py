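"""Corrected error metrics, cross-validation folds, and the grid search."""

import numpy as np
import pytest

from emg2lip import evaluation as ev
from emg2lip import synthetic_data as syn


class TestIntraobserverError:
    def test_identical_selections(self, rng):
        sel = rng.normal(size=(13, 30))
        assert ev.intraobserver_error(sel, sel) == 0.0

    def test_constant_offset(self, rng):
        """A 1 mm shift on every coordinate gives sqrt(3): the per-marker
        normaliser leaves 3 squared coordinate differences per marker."""
        sel = rng.normal(size=(13, 30))
        assert ev.intraobserver_error(sel, sel + 1.0) == pytest.approx(np.sqrt(3))

    def test_homogeneous_in_offset(self, rng):
        sel = rng.normal(size=(13, 30))
        e1 = ev.intraobserver_error(sel, sel + 1.0)
        e2 = ev.intraobserver_error(sel, sel + 2.0)
        assert e2 == pytest.approx(2 * e1)


class TestDeviationMetrics:
    def test_poses_identical_to_rest(self, rng):
        rest = rng.normal(size=(5, 30))
        poses = np.tile(rest[None], (12, 1, 1))
        d_rms, d_c = ev.deviation_metrics(poses, rest, e_obs=0.0)
        assert d_rms == 0.0 and d_c == 0.0
        with pytest.raises(ev.EvaluationDomainError):
            ev.deviation_metrics(poses, rest, e_obs=0.5)

    def test_boundary_equals_observer_error(self, rng):
        rest = rng.normal(size=(5, 30))
        poses = np.tile(rest[None], (12, 1, 1))
        poses = poses + 1.0  # d_rms = sqrt(30/10) = sqrt(3)
        d_rms, d_c = ev.deviation_metrics(poses, rest, e_obs=np.sqrt(3))
        assert d_c == pytest.approx(0.0, abs=1e-9)

    def test_single_coordinate_displacement(self, rng):
        """2 mm on one coordinate of one marker in all 60 records gives
        d_RMS = sqrt(60 * 4 / 600) = sqrt(0.4)."""
        rest = rng.normal(size=(5, 30))
        poses = np.tile(rest[None], (12, 1, 1))
        poses[:, :, 4] += 2.0
        d_rms, _ = ev.deviation_metrics(poses, rest, e_obs=0.0)
        assert d_rms == pytest.approx(np.sqrt(0.4))


class TestEstimationError:
    @pytest.mark.parametrize(
        "e_rms,expected_e_c",
        [(2.60, 2.01), (3.58, 3.17), (2.95, 2.44), (2.18, 1.42), (3.80, 3.42)],
    )
    def test_reported_corrections(self, e_rms, expected_e_c):
        """Corrected errors reproduce the reported volunteer values at the
        reported intraobserver error of 2.34 mm."""
        assert ev.corrected_error(e_rms, 2.34) == pytest.approx(expected_e_c, abs=0.005)

    def test_boundary_gives_zero(self):
        e_obs = 2.0
        assert ev.corrected_error(e_obs / np.sqrt(2), e_obs) == pytest.approx(0.0)

    def test_below_boundary_rejected(self):
        with pytest.raises(ev.EvaluationDomainError):
            ev.corrected_error(1.0, 2.0)

    def test_full_metric_with_ratio(self, rng):
        truth = rng.normal(size=(12, 5, 30))
        est = truth + rng.normal(scale=0.5, size=truth.shape)
        e_rms, e_c, e_r = ev.estimation_error(est, truth, e_obs=0.3, d_c=4.0)
        assert e_c <= e_rms
        assert e_r == pytest.approx(e_c / 4.0)


class TestUnderestimationFactor:
    def test_reported_value(self):
        assert round(ev.underestimation_factor(2.34, 0.63), 2) == 0.97

    def test_zero_measurement_error(self):
        assert ev.underestimation_factor(1.5, 0.0) == 1.0

    def test_equal_errors(self):
        assert ev.underestimation_factor(1.0, 1.0) == pytest.approx(np.sqrt(0.5))

    def test_both_zero_rejected(self):
        with pytest.raises(ev.EvaluationDomainError):
            ev.underestimation_factor(0.0, 0.0)


class TestCorrelationSummary:
    def test_perfect_estimates(self, rng):
        truth = rng.normal(size=(60, 30))
        coeffs, rho, n_excl = ev.correlation_summary(truth, truth)
        assert np.allclose(coeffs, 1.0) and rho == pytest.approx(1.0)
        assert n_excl == 0

    def test_anti_correlated(self, rng):
        truth = rng.normal(size=(60, 30))
        _, rho, _ = ev.correlation_summary(-truth, truth)
        assert rho == pytest.approx(-1.0)

    def test_white_noise_is_uncorrelated(self):
        """Null distribution: |rho| stays small for independent noise."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            _, rho, _ = ev.correlation_summary(
                r.normal(size=(60, 30)), r.normal(size=(60, 30))
            )
            assert abs(rho) < 0.5

    def test_zero_variance_coordinate_excluded(self, rng):
        truth = rng.normal(size=(60, 30))
        est = truth.copy()
        est[:, 7] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            coeffs, rho, n_excl = ev.correlation_summary(est, truth)
        assert n_excl == 1 and np.isnan(coeffs[7]) and np.isfinite(rho)


class TestCrossValidation:
    def test_training_pool_shape(self, dataset_pca):
        """Each fold trains on a 74 x 48 matrix (12 poses x 4 repetitions)."""
        train = np.array([0, 1, 2, 4])
        assert dataset_pca.joint_matrix(train).shape == (74, 48)
        assert dataset_pca.joint_matrix(np.array([3])).shape == (74, 12)

    def test_every_record_tested_once(self, dataset_pca):
        """The folds partition the records: predictions exist for all 60
        and are produced without that record's repetition in training."""
        report, estimates = ev.loo_cv(
            dataset_pca, "pca", D=9, sigma_v=0.05, return_estimates=True
        )
        assert estimates.shape == (12, 5, 30)
        assert np.all(np.isfinite(estimates))

    def test_correction_identities(self, dataset_pca):
        report = ev.loo_cv(dataset_pca, "pca", D=9, sigma_v=0.05)
        assert report.e_c**2 + 0.5 * report.e_obs**2 == pytest.approx(
            report.e_rms**2, rel=1e-12
        )
        assert report.d_c**2 + report.e_obs**2 == pytest.approx(
            report.d_rms**2, rel=1e-12
        )
        assert report.e_r == pytest.approx(report.e_c / report.d_c, rel=1e-12)

    def test_pooled_error_matches_raw_residual_recomputation(self, dataset_pca):
        report, estimates = ev.loo_cv(
            dataset_pca, "pca", D=9, sigma_v=0.05, return_estimates=True
        )
        sq = np.sum((estimates - dataset_pca.X) ** 2)
        assert report.e_rms == pytest.approx(np.sqrt(sq / 600), rel=1e-12)

    def test_repetition_order_invariance(self, dataset_pca):
        """Pooled errors must not depend on how repetitions are labelled."""
        perm = np.array([3, 0, 4, 1, 2])
        permuted = ev.VolunteerDataset(
            X=dataset_pca.X[:, perm],
            rest=dataset_pca.rest[perm],
            gbar=dataset_pca.gbar[:, perm],
            gbar_aug=dataset_pca.gbar_aug[:, perm],
            e_obs=dataset_pca.e_obs,
        )
        a = ev.loo_cv(dataset_pca, "pca", D=9, sigma_v=0.05)
        b = ev.loo_cv(permuted, "pca", D=9, sigma_v=0.05)
        assert a.e_rms == pytest.approx(b.e_rms, rel=1e-10)

    def test_grnn_requires_series(self, dataset_pca):
        stripped = ev.VolunteerDataset(
            X=dataset_pca.X, rest=dataset_pca.rest, gbar=dataset_pca.gbar,
            gbar_aug=dataset_pca.gbar_aug, e_obs=dataset_pca.e_obs,
        )
        with pytest.raises(ev.IncompleteDesignError):
            ev.loo_cv(stripped, "grnn")

    def test_sweep_matches_single_setting_cv(self, dataset_pca):
        """The vectorised parameter sweep agrees with the plain fold loop."""
        e_c = ev.pca_param_sweep(dataset_pca, Ds=(9,), sigma_vs=(0.05,))
        report = ev.loo_cv(dataset_pca, "pca", D=9, sigma_v=0.05)
        assert e_c[0, 0] == pytest.approx(report.e_c, rel=1e-9)

    def test_grnn_sweep_matches_single_cv(self, dataset_grnn):
        e_c = ev.grnn_param_sweep(dataset_grnn, alphas=(2.0,))
        report = ev.loo_cv(dataset_grnn, "grnn", alpha=2.0)
        assert e_c[0] == pytest.approx(report.e_c, rel=1e-9)


class TestSettingsGrid:
    def test_full_grid_size(self):
        grid = ev.feature_settings_grid()
        assert len(grid) == 60
        assert len(set(grid)) == 60

    def test_wamp_thresholds_present(self):
        grid = ev.feature_settings_grid()
        slims = {s.s_lim for s in grid if s.feature_type == "WAMP"}
        assert slims == {10.0, 20.0}


def _two_volunteer_datasets():
    settings = [
        ev.FeatureSetting("unipolar", "RMS", 300),
        ev.FeatureSetting("bipolar", "RMS", 300),
    ]
    datasets = {}
    for vol_idx, seed in enumerate((31, 32)):
        vol = syn.make_volunteer(seed, vol_idx, noise_scale=0.0, sigma_x=0.0)
        datasets[vol_idx] = {
            s: syn.build_exact_dataset(vol, s.configuration) for s in settings
        }
    return datasets


class TestGridSearch:
    @pytest.fixture(scope="class")
    def search(self):
        return ev.grid_search(
            _two_volunteer_datasets(), "pca", Ds=(5, 9), sigma_vs=(0.0, 0.05)
        )

    def test_argmin_matches_table_scan(self, search):
        best_by_scan = min(
            (r for r in search.results if np.isfinite(r.e_c_average)),
            key=lambda r: r.e_c_average,
        )
        assert search.best.e_c_average == pytest.approx(best_by_scan.e_c_average)

    def test_grid_is_fully_enumerated(self, search):
        assert len(search.results) == 2 * 2 * 2  # settings x D x sigma_v

    def test_volunteer_specific_never_worse(self, search):
        """A volunteer's own optimum cannot exceed their error at the
        volunteer-independent settings."""
        for vol, best in search.best_per_volunteer.items():
            assert (
                best.e_c_per_volunteer[vol]
                <= search.best.e_c_per_volunteer[vol] + 1e-12
            )

    def test_single_volunteer_reduces_to_own_optimum(self):
        datasets = _two_volunteer_datasets()
        single = {0: datasets[0]}
        out = ev.grid_search(single, "pca", Ds=(5, 9), sigma_vs=(0.0, 0.05))
        assert out.best.e_c_average == pytest.approx(
            out.best_per_volunteer[0].e_c_per_volunteer[0]
        )

    def test_grnn_route(self):
        out = ev.grid_search(_two_volunteer_datasets(), "grnn", alphas=(1.0, 2.0))
        assert len(out.results) == 2 * 2
        assert np.isfinite(out.best.e_c_average)
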