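"""KDE smoothing, three-Gaussian fitting, and voxel classification."""

import numpy as np
import pytest

from brainseg.brain_extraction import IntensityHistogram, PeakTriple
from brainseg.histogram_segmentation import (
    GaussianMixtureParams,
    KDEConfig,
    _model_and_jac,
    _theta_from_params,
    classify,
    fit_mixture,
    initialize_params,
    kde_smooth,
    mixture_model,
)
from brainseg.volumes_io import LABEL_CSF, LABEL_GM, LABEL_OTHER, LABEL_WM, Volume

TRUE = GaussianMixtureParams(p=[900.0, 2400, 1900], mu=[52.0, 138, 197], sigma=[9.0, 11, 13])
START = GaussianMixtureParams(p=[500.0, 2000, 1500], mu=[40.0, 120, 210], sigma=[5.0, 15, 8])


class TestKDE:
    def test_tiny_bandwidth_returns_normalized_input(self, rng):
        counts = rng.integers(0, 100, 64).astype(float)
        out = kde_smooth(IntensityHistogram(counts), KDEConfig(bandwidth=0.01))
        np.testing.assert_allclose(out, counts / counts.sum())

    def test_single_spike_becomes_discretized_gaussian(self):
        counts = np.zeros(256)
        counts[128] = 1000
        out = kde_smooth(IntensityHistogram(counts), KDEConfig(bandwidth=5.0))
        x = np.arange(256)
        mean = (out * x).sum()
        sd = np.sqrt((out * (x - mean) ** 2).sum())
        assert mean == pytest.approx(128, abs=0.01)
        assert sd == pytest.approx(5.0, rel=0.01)

    def test_output_sums_to_one(self, rng):
        for _ in range(5):
            counts = rng.integers(0, 100, 128).astype(float) + 1
            out = kde_smooth(IntensityHistogram(counts), KDEConfig(bandwidth=3.0))
            assert out.sum() == pytest.approx(1.0)


class TestInitialize:
    def test_initial_means_near_truth_on_synthetic_histogram(self):
        i = np.arange(256.0)
        hist = IntensityHistogram(mixture_model(i, TRUE))
        peaks = PeakTriple(
            mu_csf=52, mu_gm=138, mu_wm=197, sigmas=(9.0, 11.0, 13.0)
        )
        v0 = initialize_params(hist, peaks)
        np.testing.assert_allclose(v0.mu, TRUE.mu, atol=2.0)
        assert np.all(v0.p > 0) and np.all(v0.sigma > 0)

    def test_valley_fallback_peaks_accepted(self):
        i = np.arange(256.0)
        hist = IntensityHistogram(mixture_model(i, TRUE))
        peaks = PeakTriple(
            mu_csf=20, mu_gm=138, mu_wm=197, sigmas=(11.0, 11.0, 13.0),
            csf_is_fallback=True,
        )
        v0 = initialize_params(hist, peaks)
        assert v0.mu[0] == 20

    def test_flat_histogram_rejected(self):
        hist = IntensityHistogram(np.zeros(64))
        peaks = PeakTriple(mu_csf=10, mu_gm=30, mu_wm=50)
        with pytest.raises(ValueError):
            initialize_params(hist, peaks)


class TestFit:
    def test_noiseless_recovery_within_half_gray_level(self):
        i = np.arange(256.0)
        hist = IntensityHistogram(mixture_model(i, TRUE))
        fr = fit_mixture(hist, START)
        assert fr.converged
        assert np.abs(fr.v_star.mu - TRUE.mu).max() < 0.5
        assert np.abs(fr.v_star.sigma / TRUE.sigma - 1).max() < 0.05

    def test_sampled_histogram_recovery_within_two_gray_levels(self):
        rng = np.random.default_rng(77)
        i = np.arange(256.0)
        probs = mixture_model(i, TRUE)
        probs /= probs.sum()
        draws = rng.choice(256, size=10**6, p=probs)
        hist = IntensityHistogram(np.bincount(draws, minlength=256).astype(float))
        fr = fit_mixture(hist, START)
        assert np.abs(fr.v_star.mu - TRUE.mu).max() < 2.0

    def test_descent_from_any_valid_start(self):
        i = np.arange(256.0)
        x = np.exp(-0.5 * ((i - 120) / 15.0) ** 2) * 3000  # single-Gaussian target
        hist = IntensityHistogram(x)
        v0 = GaussianMixtureParams(p=[10.0, 3000, 10], mu=[10.0, 120, 250], sigma=[2.0, 15, 2])
        fr = fit_mixture(hist, v0)
        sse0 = ((mixture_model(i, v0) - x) ** 2).sum()
        assert fr.sse <= sse0

    def test_fitted_means_stay_ordered(self):
        i = np.arange(256.0)
        hist = IntensityHistogram(mixture_model(i, TRUE))
        fr = fit_mixture(hist, START)
        assert fr.v_star.mu[0] < fr.v_star.mu[1] < fr.v_star.mu[2]

    def test_analytic_jacobian_matches_finite_differences(self):
        i = np.arange(0.0, 64.0)
        v = GaussianMixtureParams(p=[100.0, 300, 200], mu=[10.0, 30, 50], sigma=[3.0, 4, 5])
        theta = _theta_from_params(v, 64)
        model, jac = _model_and_jac(theta, i, 64)
        eps = 1e-6
        for k in range(9):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            mp, _ = _model_and_jac(tp, i, 64)
            mm, _ = _model_and_jac(tm, i, 64)
            fd = (mp - mm) / (2 * eps)
            np.testing.assert_allclose(jac[:, k], fd, rtol=1e-4, atol=1e-6)


class TestClassify:
    def setup_method(self):
        self.v = GaussianMixtureParams(
            p=[1000.0, 1000, 1000], mu=[40.0, 110, 160], sigma=[8.0, 8, 8]
        )

    def test_mode_centers_get_their_class(self):
        data = np.full((4, 4, 4), 110.0)
        out = classify(Volume(data), np.ones((4, 4, 4), bool), self.v)
        assert np.all(out.labels.labels == LABEL_GM)

    def test_equal_likelihood_crossing_ties_to_lower_class(self):
        crossing = 135.0  # midpoint of GM/WM with equal p and sigma
        data = np.full((3, 3, 3), crossing)
        out = classify(Volume(data), np.ones((3, 3, 3), bool), self.v)
        assert np.all(out.labels.labels == LABEL_GM)
        assert np.all(out.confidence[out.brain_mask] == pytest.approx(1.0))
        assert out.ambiguous.all()

    def test_bright_voxels_become_other(self):
        data = np.full((3, 3, 3), 110.0)
        data[1, 1, 1] = 160 + 3 * 8 + 5  # beyond mu3 + 3 sigma3
        out = classify(Volume(data), np.ones((3, 3, 3), bool), self.v)
        assert out.labels.labels[1, 1, 1] == LABEL_OTHER

    def test_argmax_matches_brute_force_on_random_volume(self, rng):
        data = rng.uniform(0, 200, size=(16, 16, 16))
        mask = rng.random((16, 16, 16)) > 0.2
        out = classify(Volume(data), mask, self.v)
        lab_map = np.array([LABEL_CSF, LABEL_GM, LABEL_WM])
        for x, y, z in rng.integers(0, 16, size=(50, 3)):
            if not mask[x, y, z]:
                assert out.labels.labels[x, y, z] == 0
                continue
            i = data[x, y, z]
            lik = self.v.p * np.exp(-0.5 * ((i - self.v.mu) / self.v.sigma) ** 2)
            expect = lab_map[np.argmax(lik)]
            if i > self.v.mu[2] + 3 * self.v.sigma[2]:
                expect = LABEL_OTHER
            assert out.labels.labels[x, y, z] == expect

    def test_decision_is_piecewise_constant_in_intensity(self):
        # sweep intensity: labels must change at most 3 times (C1->C2->C3->C4)
        i = np.linspace(0, 220, 2000)
        data = np.tile(i, (1, 1, 1)).reshape(1, 1, -1)
        out = classify(Volume(data), np.ones_like(data, dtype=bool), self.v)
        labs = out.labels.labels.ravel()
        assert (np.diff(labs) != 0).sum() <= 3

    def test_ambiguous_includes_boundary_neighbors(self):
        data = np.full((8, 8, 8), 110.0)
        data[4:, :, :] = 160.0  # sharp GM/WM interface
        out = classify(Volume(data), np.ones((8, 8, 8), bool), self.v)
        assert out.ambiguous[3, 4, 4] and out.ambiguous[4, 4, 4]
        assert not out.ambiguous[0, 4, 4] and not out.ambiguous[7, 4, 4]
        assert not np.any(out.ambiguous & ~out.brain_mask)

    def test_model_reproduces_three_mode_structure(self):
        i = np.arange(256.0)
        hist = IntensityHistogram(mixture_model(i, TRUE))
        fr = fit_mixture(hist, START)
        fitted = mixture_model(i, fr.v_star)
        from scipy.signal import find_peaks as sfp

        peaks, _ = sfp(fitted, prominence=fitted.max() * 0.01)
        assert len(peaks) == 3
        for mu, pk in zip(fr.v_star.mu, peaks):
            assert abs(mu - pk) <= 2.0
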