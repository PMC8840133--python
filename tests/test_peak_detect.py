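import numpy as np
import pytest

from deepmaldi.peak_detect import (
    PeakCandidate,
    assign_clusters,
    convolve_with_shape,
    estimate_noise,
    find_candidates,
    fit_peaks,
)
from deepmaldi.peak_shape import AsymmetricGaussian, eval_asym_gaussian
from deepmaldi.synth import make_spectrum, tof_grid

from conftest import flat_truth


class TestConvolveWithShape:
    def test_unit_matching_peak_gives_unit_response(self, shape, grid):
        m0 = 8000.0
        g = AsymmetricGaussian(1.0, m0, float(shape.width(m0, "left")),
                               float(shape.width(m0, "right")))
        fine = eval_asym_gaussian(g, grid)
        conv = convolve_with_shape(fine, grid, shape)
        i = int(np.argmax(conv))
        assert abs(grid[i] - m0) <= 2 * np.median(np.diff(grid))
        assert conv[i] == pytest.approx(1.0, rel=0.02)

    def test_smooths_white_noise(self, shape, grid):
        rng = np.random.default_rng(0)
        noise = rng.normal(0.0, 1.0, len(grid))
        conv = convolve_with_shape(noise, grid, shape)
        assert conv.std() < noise.std()

    def test_zero_in_zero_out(self, shape, grid):
        conv = convolve_with_shape(np.zeros(len(grid)), grid, shape)
        assert np.all(conv == 0)


class TestEstimateNoise:
    def test_iid_noise_level_recovered(self, shape, grid):
        rng = np.random.default_rng(1)
        noise = estimate_noise(rng.normal(0.0, 2.0, len(grid)), grid, shape)
        assert 1.6 < np.median(noise) < 2.4

    def test_constant_signal_floored(self, shape, grid):
        noise = estimate_noise(np.full(len(grid), 5.0), grid, shape)
        assert np.all(noise > 0)
        assert np.median(noise) < 1e-6  # floored near machine epsilon scale

    def test_scales_linearly(self, shape, grid):
        rng = np.random.default_rng(2)
        y = rng.normal(0.0, 3.0, len(grid))
        n1 = estimate_noise(y, grid, shape)
        n2 = estimate_noise(10.0 * y, grid, shape)
        np.testing.assert_allclose(n2, 10.0 * n1, rtol=1e-9)


class TestFindCandidates:
    def test_single_strong_peak_found_once(self, shape):
        truth = flat_truth([9000.0], [100.0], shape, noise_sd=1.0, seed=3)
        spec = make_spectrum(truth)
        cands = find_candidates(spec.intensity - np.median(spec.intensity),
                                spec.mz, shape, snr_min=10)
        fw = float(shape.width(9000.0, "fwhm"))
        near = [c for c in cands if abs(c.m0 - 9000.0) < fw / 4]
        assert len(near) == 1

    def test_two_separated_peaks_found(self, shape):
        fw = float(shape.width(9000.0, "fwhm"))
        pos = [9000.0, 9000.0 + 3 * fw]
        truth = flat_truth(pos, [50.0, 50.0], shape, noise_sd=1.0, seed=4)
        spec = make_spectrum(truth)
        cands = find_candidates(spec.intensity - np.median(spec.intensity),
                                spec.mz, shape, snr_min=10)
        hits = [c for c in cands if min(abs(c.m0 - p) for p in pos) < fw / 4]
        assert len(hits) == 2

    def test_pure_noise_false_positive_rate(self, shape, grid):
        # expected false candidates <= 1 per 10,000 grid points at SNR > 10
        rng = np.random.default_rng(5)
        total = 0
        for _ in range(3):
            y = rng.normal(0.0, 1.0, len(grid))
            total += len(find_candidates(y, grid, shape, snr_min=10))
        assert total / (3 * len(grid)) <= 1e-4


class TestAssignClusters:
    def _cand(self, m0, amp):
        return PeakCandidate(m0=m0, snr=50.0, amplitude=amp)

    def test_far_apart_peaks_stay_isolated(self, shape):
        fw = float(shape.width(10000.0, "fwhm"))
        clusters, isolated = assign_clusters(
            [self._cand(10000.0, 100.0), self._cand(10000.0 + 5 * fw, 100.0)], shape)
        assert clusters == [] and len(isolated) == 2

    def test_close_centers_form_cluster(self, shape):
        fw = float(shape.width(10000.0, "fwhm"))
        clusters, isolated = assign_clusters(
            [self._cand(10000.0, 100.0), self._cand(10000.0 + 0.4 * fw, 100.0)], shape)
        assert len(clusters) == 1 and clusters[0].N == 2 and isolated == []
        assert all(c.influenced for c in clusters[0].members)

    def test_tail_rule_links_unequal_pair(self, shape):
        # a 100:1 pair 1.5 FWHM apart: the tall peak's tail at the small peak's
        # center exceeds 10% of the small peak's amplitude
        m0 = 10000.0
        fw = float(shape.width(m0, "fwhm"))
        tall = self._cand(m0, 1000.0)
        small = self._cand(m0 + 1.5 * fw, 10.0)
        g_tall = AsymmetricGaussian(1000.0, m0, float(shape.width(m0, "left")),
                                    float(shape.width(m0, "right")))
        assert float(eval_asym_gaussian(g_tall, small.m0)) > 0.1 * small.amplitude
        clusters, isolated = assign_clusters([tall, small], shape)
        assert len(clusters) == 1 and clusters[0].N == 2


class TestFitPeaks:
    def test_noiseless_isolated_amplitude_exact(self, shape, grid):
        m0, a0 = 12000.0, 250.0
        g = AsymmetricGaussian(a0, m0, float(shape.width(m0, "left")),
                               float(shape.width(m0, "right")))
        fine = eval_asym_gaussian(g, grid)
        cand = PeakCandidate(m0=m0, snr=100.0, amplitude=a0)
        for mode in (True, False):
            peaks = fit_peaks(fine, grid, [], [cand], shape, fit_positions=mode)
            assert peaks[0].gaussian.amplitude == pytest.approx(a0, rel=1e-6)

    def test_noiseless_doublet_joint_fit(self, shape, grid):
        # separation 0.6 FWHM, amplitude ratio 5:1 -> both recovered within 1%
        m1 = 12000.0
        fw = float(shape.width(m1, "fwhm"))
        m2 = m1 + 0.6 * fw
        a1, a2 = 500.0, 100.0
        fine = np.zeros(len(grid))
        for m, a in ((m1, a1), (m2, a2)):
            fine += eval_asym_gaussian(
                AsymmetricGaussian(a, m, float(shape.width(m, "left")),
                                   float(shape.width(m, "right"))), grid)
        cands = [PeakCandidate(m0=m1, snr=50, amplitude=a1),
                 PeakCandidate(m0=m2, snr=50, amplitude=a2)]
        clusters, isolated = assign_clusters(cands, shape)
        assert len(clusters) == 1
        peaks = fit_peaks(fine, grid, clusters, isolated, shape, fit_positions=False)
        got = sorted([p.gaussian.amplitude for p in peaks], reverse=True)
        assert got[0] == pytest.approx(a1, rel=0.01)
        assert got[1] == pytest.approx(a2, rel=0.01)

    def test_extraction_at_empty_position_near_zero(self, shape, grid):
        rng = np.random.default_rng(7)
        fine = rng.normal(0.0, 1.0, len(grid))
        cand = PeakCandidate(m0=15000.0, snr=0.5, amplitude=0.0)
        peaks = fit_peaks(fine, grid, [], [cand], shape, fit_positions=False)
        assert peaks[0].gaussian.amplitude < 3.0  # below the noise level
        assert peaks[0].gaussian.amplitude >= 0.0

    def test_extraction_amplitudes_non_negative(self, shape, grid):
        rng = np.random.default_rng(8)
        fine = rng.normal(0.0, 1.0, len(grid))
        cands = [PeakCandidate(m0=m, snr=1.0, amplitude=0.0)
                 for m in np.linspace(5000, 25000, 30)]
        peaks = fit_peaks(fine, grid, [], cands, shape, fit_positions=False)
        assert all(p.gaussian.amplitude >= 0 for p in peaks)
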