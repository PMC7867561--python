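"""Observed-CSD estimation and variational-Laplace subject inversion."""

import numpy as np
import pytest

import fsdcm
from fsdcm import ConnectionParams, PriorSpec, SpectralConfig, TimeSeriesData


def _white_series(n, seed, k=2):
    rng = np.random.default_rng(seed)
    return TimeSeriesData(rng.standard_normal((n, k)), 1.0,
                          tuple(f"r{i}" for i in range(k)))


class TestEstimateCSD:
    def test_independent_series_have_low_coherence(self):
        csd = fsdcm.estimate_csd(_white_series(4096, 0))
        coh = np.abs(csd.csd[:, 0, 1]) ** 2 / (
            csd.csd[:, 0, 0].real * csd.csd[:, 1, 1].real)
        assert coh.mean() < 0.2

    def test_duplicated_region_has_unit_coherence(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4096)
        values = np.column_stack([x, x + 1e-3 * rng.standard_normal(x.size)])
        csd = fsdcm.estimate_csd(TimeSeriesData(values, 1.0, ("a", "b")))
        coh = np.abs(csd.csd[:, 0, 1]) ** 2 / (
            csd.csd[:, 0, 0].real * csd.csd[:, 1, 1].real)
        assert coh.min() > 0.99

    def test_ar1_spectrum_matches_closed_form(self):
        phi, n = 0.9, 8192
        rng = np.random.default_rng(2)
        e = rng.standard_normal((n, 2))
        x = np.empty_like(e)
        x[0] = e[0]
        for t in range(1, n):
            x[t] = phi * x[t - 1] + e[t]
        csd = fsdcm.estimate_csd(TimeSeriesData(x, 1.0, ("a", "b")))
        f = csd.freqs
        closed = 2.0 / np.abs(1 - phi * np.exp(-2j * np.pi * f)) ** 2
        for d in range(2):
            rel = np.abs(csd.csd[:, d, d].real - closed) / closed
            assert rel.max() < 0.2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="4 x AR order"):
            fsdcm.estimate_csd(_white_series(31, 3))

    def test_estimate_is_hermitian_psd_with_dof_attached(self):
        csd = fsdcm.estimate_csd(_white_series(360, 4))
        assert csd.is_psd()
        assert csd.effective_dof == 8 * 4 + 3

    def test_uncertainty_propagation_shapes(self):
        csd = fsdcm.estimate_csd(_white_series(360, 5), with_uncertainty=True)
        n = 4 * csd.freqs.size
        assert csd.feature_sd.shape == (n,)
        assert csd.feature_cov.shape == (n, n)
        assert (csd.feature_sd > 0).all()


class TestInvertSubject:
    def test_noise_free_self_consistency(self):
        theta_star = np.array([0.4, -0.3, 0.2, 0.1])
        observed = fsdcm.predicted_csd(ConnectionParams.from_array(theta_star))
        post = fsdcm.invert_subject(observed, subject_id="clean")
        sd = np.sqrt(np.diag(post.covariance))
        assert np.all(np.abs(post.mean - theta_star) <= 3 * sd + 1e-3)
        assert post.explained_variance_pct >= 95.0
        assert post.converged

    def test_recovery_at_the_prior_mean(self):
        observed = fsdcm.predicted_csd(ConnectionParams())
        post = fsdcm.invert_subject(observed)
        assert np.abs(post.mean).max() < 0.2

    def test_zero_data_weight_returns_the_prior(self):
        observed = fsdcm.predicted_csd(ConnectionParams(0.3, 0.3, -0.3, 0.0))
        priors = PriorSpec()
        post = fsdcm.invert_subject(observed, priors, data_weight=0.0)
        assert post.mean == pytest.approx(priors.theta_mean, abs=1e-8)
        assert post.covariance == pytest.approx(priors.theta_cov, abs=1e-8)

    def test_free_energy_non_decreasing(self, noisy_subject_posterior):
        traj = np.array(noisy_subject_posterior.f_trajectory)
        assert traj.size >= 2
        assert np.all(np.diff(traj) >= -1e-9)

    def test_fit_beats_prior_only_evaluation(self):
        # model-generated data: fitting must improve the evidence bound
        improved = []
        for seed in range(8):
            ts = fsdcm.generate_subject_series(
                ConnectionParams(0.2, -0.2, 0.1, 0.1), seed=50 + seed)
            post = fsdcm.invert_subject(fsdcm.estimate_csd(ts))
            improved.append(post.improved)
        assert np.mean(improved) >= 0.95

    def test_posterior_covariance_psd_and_scale_factors_positive(
            self, noisy_subject_posterior):
        w = np.linalg.eigvalsh(noisy_subject_posterior.covariance)
        assert w.min() >= 0
        assert (noisy_subject_posterior.scale_factors > 0).all()

    def test_non_psd_observation_rejected(self):
        good = fsdcm.predicted_csd(ConnectionParams())
        bad = good.csd.copy()
        bad[0] = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        from fsdcm.model import CrossSpectralData
        with pytest.raises(ValueError, match="semidefinite"):
            fsdcm.invert_subject(CrossSpectralData(good.freqs, bad))

    def test_posterior_json_roundtrip(self, tmp_path, noisy_subject_posterior):
        path = tmp_path / "post.json"
        noisy_subject_posterior.save(path)
        import json
        back = fsdcm.SubjectPosterior.from_dict(json.loads(path.read_text()))
        assert back.mean == pytest.approx(noisy_subject_posterior.mean)
        assert back.free_energy == noisy_subject_posterior.free_energy


class TestExplainedVariance:
    def test_perfect_prediction_is_100(self):
        csd = fsdcm.predicted_csd(ConnectionParams())
        assert fsdcm.explained_variance(csd, csd) == pytest.approx(100.0)

    @staticmethod
    def _constant_feature_csd(freqs, c):
        """A CSD whose every feature (S11, S22, Re/Im S12) equals ``c``."""
        from fsdcm.model import CrossSpectralData
        S = np.empty((freqs.size, 2, 2), dtype=complex)
        S[:, 0, 0] = S[:, 1, 1] = c
        S[:, 0, 1] = c + 1j * c
        S[:, 1, 0] = c - 1j * c
        return CrossSpectralData(freqs, S)

    def test_constant_mean_prediction_is_0(self):
        observed = fsdcm.predicted_csd(ConnectionParams())
        mean = float(observed.feature_vector().mean())
        predicted = self._constant_feature_csd(observed.freqs, mean)
        assert fsdcm.explained_variance(observed, predicted) == pytest.approx(
            0.0, abs=1e-8)

    def test_zero_variance_observation_rejected(self):
        freqs = fsdcm.default_frequencies()
        obs = self._constant_feature_csd(freqs, 1.0)
        with pytest.raises(ValueError, match="zero variance"):
            fsdcm.explained_variance(obs, obs)

    def test_mismatched_grids_rejected(self):
        a = fsdcm.predicted_csd(ConnectionParams())
        b = fsdcm.predicted_csd(ConnectionParams(),
                                freqs=fsdcm.default_frequencies(16))
        with pytest.raises(ValueError, match="frequency grid"):
            fsdcm.explained_variance(a, b)


class TestCohortDiagnostics:
    def test_published_fit_quality_table(self, ev_table):
        diag = fsdcm.summarize_explained_variance(
            ev_table.subject_id.astype(str), ev_table.explained_variance_pct)
        assert round(diag.mean_ev_pct, 2) == 25.01
        assert round(diag.sd_ev_pct, 2) == 14.22
        assert set(diag.flagged_subjects) == {"6", "8"}
        assert diag.acceptable

    def test_single_good_subject(self):
        diag = fsdcm.summarize_explained_variance(["s1"], [50.0])
        assert diag.mean_ev_pct == 50.0
        assert diag.sd_ev_pct is None
        assert diag.flagged_subjects == ()

    def test_threshold_is_inclusive(self):
        diag = fsdcm.summarize_explained_variance(
            ["a", "b", "c"], [10.0, 10.0, 10.0])
        assert diag.mean_ev_pct == 10.0
        assert diag.flagged_subjects == ()
        assert diag.acceptable
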