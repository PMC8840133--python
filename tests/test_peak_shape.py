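import numpy as np
import pytest

from deepmaldi.peak_shape import (
    AsymmetricGaussian,
    PeakShapeModel,
    WidthTrend,
    calibrate_peak_shape,
    default_shape_model,
    eval_asym_gaussian,
    fit_isolated_peak,
    width_at,
)
from deepmaldi.synth import make_spectrum

from conftest import flat_truth


class TestAsymmetricGaussian:
    def test_peak_maximum(self):
        g = AsymmetricGaussian(1.0, 5000.0, 2.0, 2.0)
        assert eval_asym_gaussian(g, 5000.0) == 1.0

    def test_half_maximum_at_hwhm_both_sides(self):
        g = AsymmetricGaussian(2.0, 5000.0, 1.5, 3.0)
        assert eval_asym_gaussian(g, 5003.0) == pytest.approx(1.0)  # m0 + sigma_R
        assert eval_asym_gaussian(g, 4998.5) == pytest.approx(1.0)  # m0 - sigma_L
        g1 = AsymmetricGaussian(1.0, 5000.0, 1.5, 3.0)
        assert eval_asym_gaussian(g1, 5003.0) == pytest.approx(0.5)

    def test_continuous_at_center(self):
        g = AsymmetricGaussian(3.0, 8000.0, 1.0, 4.0)
        m = np.array([8000.0 - 1e-9, 8000.0, 8000.0 + 1e-9])
        v = eval_asym_gaussian(g, m)
        assert np.all(np.abs(v - 3.0) < 1e-8)

    def test_positive_widths_required(self):
        with pytest.raises(ValueError):
            AsymmetricGaussian(1.0, 5000.0, 0.0, 1.0)


class TestWidthTrend:
    def test_linear_branch_arithmetic(self):
        t = WidthTrend(a0=1.0, a1=1e-4, c0=0, c1=0, c2=1, m_int=np.inf)
        assert t(10000.0) == pytest.approx(2.0)

    def test_pure_quadratic_when_m_int_zero(self):
        # the convention for instruments with no linear regime
        t = WidthTrend(a0=99.0, a1=99.0, c0=1.0, c1=1e-5, c2=1e-9, m_int=0.0)
        m = np.array([4000.0, 20000.0])
        np.testing.assert_allclose(t(m), 1.0 + 1e-5 * m + 1e-9 * m**2)

    def test_width_at_rejects_nonpositive(self, shape):
        bad = PeakShapeModel(
            left=WidthTrend(a0=-10.0, a1=0.0, c0=-10.0, c1=0, c2=0, m_int=1e9),
            right=shape.right, fwhm=shape.fwhm)
        with pytest.raises(ValueError, match="non-positive"):
            width_at(bad, 5000.0, "left")

    def test_default_model_sides_sum_to_fwhm(self, shape):
        m = np.linspace(3000, 30000, 300)
        np.testing.assert_allclose(
            shape.width(m, "left") + shape.width(m, "right"),
            shape.width(m, "fwhm"), rtol=1e-12)

    def test_json_roundtrip(self, shape, tmp_path):
        shape.to_json(tmp_path / "m.json")
        back = PeakShapeModel.from_json(tmp_path / "m.json")
        m = np.linspace(3000, 30000, 50)
        for side in ("left", "right", "fwhm"):
            np.testing.assert_allclose(back.width(m, side), shape.width(m, side))


class TestFitIsolatedPeak:
    def test_noiseless_parameters_recovered(self, shape):
        truth = flat_truth([8000.0], [100.0], shape)
        spec = make_spectrum(truth)
        fit = fit_isolated_peak(spec, (7980.0, 8020.0))
        g = fit.gaussian
        assert g.amplitude == pytest.approx(100.0, rel=1e-6)
        assert g.center == pytest.approx(8000.0, abs=1e-3)
        assert g.sigma_l == pytest.approx(shape.width(8000.0, "left"), rel=1e-3)
        assert g.sigma_r == pytest.approx(shape.width(8000.0, "right"), rel=1e-3)

    def test_amplitude_recovery_under_noise(self, shape):
        # Monte-Carlo: 1% noise, median amplitude error < 2%
        errs = []
        for k in range(50):
            truth = flat_truth([8000.0], [100.0], shape, noise_sd=1.0, seed=1000 + k)
            spec = make_spectrum(truth)
            fit = fit_isolated_peak(spec, (7980.0, 8020.0))
            errs.append(abs(fit.gaussian.amplitude - 100.0) / 100.0)
        assert np.median(errs) < 0.02

    def test_asymmetric_fit_beats_symmetric(self, shape):
        # mirrors the observed large symmetric-fit residual on real peaks
        for m0 in (5000.0, 12000.0, 25000.0):
            truth = flat_truth([m0], [500.0], shape, noise_sd=1.0, seed=int(m0))
            spec = make_spectrum(truth)
            w = (m0 - 40.0, m0 + 40.0)
            asym = fit_isolated_peak(spec, w)
            sym = fit_isolated_peak(spec, w, symmetric=True)
            assert asym.abs_residual < sym.abs_residual

    def test_too_few_points_above_threshold(self, shape):
        truth = flat_truth([8000.0], [100.0], shape)
        spec = make_spectrum(truth)
        with pytest.raises(ValueError, match="at least 5"):
            fit_isolated_peak(spec, (7995.0, 8005.0), threshold_frac=0.999)


def _seed_windows(positions):
    return [(m - 25.0, m + 25.0) for m in positions]


class TestCalibration:
    SEED_POS = np.linspace(3300.0, 29500.0, 19)

    def _spectrum(self, shape, seed=0, noise=0.0):
        truth = flat_truth(self.SEED_POS, np.full(19, 5e4), shape,
                           noise_sd=noise, n_points=60000, seed=seed)
        return make_spectrum(truth)

    def test_known_trend_recovered_within_3pct(self, shape):
        model = calibrate_peak_shape(self._spectrum(shape), _seed_windows(self.SEED_POS))
        test_m = np.linspace(3500.0, 29500.0, 10)
        for side in ("left", "right", "fwhm"):
            rel = np.abs(model.width(test_m, side) - shape.width(test_m, side)) \
                / shape.width(test_m, side)
            assert rel.max() < 0.03, side

    def test_right_hwhm_consistently_wider(self, shape):
        # calibrated on data generated with sigma_R > sigma_L
        model = calibrate_peak_shape(self._spectrum(shape), _seed_windows(self.SEED_POS))
        m = np.linspace(3300.0, 29500.0, 40)
        assert np.all(model.width(m, "right") >= model.width(m, "left"))

    def test_replicate_averaging_idempotent(self, shape):
        spec = self._spectrum(shape)
        single = calibrate_peak_shape(spec, _seed_windows(self.SEED_POS))
        averaged = calibrate_peak_shape([spec] * 12, _seed_windows(self.SEED_POS))
        m = np.linspace(3300.0, 29500.0, 20)
        for side in ("left", "right", "fwhm"):
            np.testing.assert_allclose(averaged.width(m, side), single.width(m, side),
                                       rtol=1e-10)

    def test_low_mass_only_seeds_rejected(self, shape):
        low = np.linspace(3300.0, 12000.0, 10)
        truth = flat_truth(low, np.full(10, 5e4), shape, n_points=60000)
        spec = make_spectrum(truth)
        with pytest.raises(ValueError, match="quadratic"):
            calibrate_peak_shape(spec, _seed_windows(low))

    def test_too_few_seed_peaks_rejected(self, shape):
        spec = self._spectrum(shape)
        with pytest.raises(ValueError, match=">=8"):
            calibrate_peak_shape(spec, _seed_windows(self.SEED_POS[:5]))

    def test_fallback_m_int_when_no_intersection(self, shape):
        spec = self._spectrum(shape)
        with pytest.warns(UserWarning, match="falling back"):
            model = calibrate_peak_shape(spec, _seed_windows(self.SEED_POS),
                                         intersection_range=(13000.0, 13001.0))
        assert model.fwhm.m_int == 15000.0
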