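"""Pseudo-Voigt deconvolution: lineshape, seeding, fitting, assignment."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from qnmrbench.deconv import (
    DeconvolutionResult,
    PseudoVoigtPeak,
    fit_peaks,
    local_baseline,
    metabolite_area_from_fit,
    pseudo_voigt_area,
    pseudo_voigt_value,
    seed_peaks_second_derivative,
)
from qnmrbench.library import Line, MetaboliteDef, Multiplet
from qnmrbench.spectrum import Spectrum1D, make_axis


def _segment(y, hi=1.4, lo=1.2):
    x = make_axis((hi, lo), y.size)
    return Spectrum1D(ppm_axis=x, intensity=y)


def _pv_on(x, center, h, w, eta):
    return pseudo_voigt_value(x, center, h, w, eta)


class TestPseudoVoigtShape:
    @pytest.mark.parametrize(
        "eta,expected",
        [
            (1.0, math.pi / 2.0),
            (0.0, math.sqrt(math.pi / (4 * math.log(2)))),
            (0.5, (math.pi / 2.0 + math.sqrt(math.pi / (4 * math.log(2)))) / 2.0),
        ],
    )
    def test_closed_form_area_unit_peak(self, eta, expected):
        assert pseudo_voigt_area(1.0, 1.0, eta) == pytest.approx(expected, rel=1e-12)

    def test_area_matches_quadrature(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            h = rng.uniform(0.1, 10.0)
            w = rng.uniform(0.001, 0.1)
            eta = rng.uniform(0.0, 1.0)
            numeric, _ = quad(
                lambda d: pseudo_voigt_value(d, 0.0, h, w, eta),
                -50 * w, 50 * w, limit=400,
            )
            # add back the analytic Lorentzian tail beyond +-50 w
            tail = h * w * eta * (math.pi / 2.0 - math.atan(100.0))
            closed = pseudo_voigt_area(h, w, eta)
            assert abs((numeric + tail) - closed) <= 1e-8 * closed

    @pytest.mark.parametrize("eta", [0.0, 1.0])
    def test_limits_reduce_to_pure_shapes(self, eta):
        x = np.linspace(-0.05, 0.05, 501)
        val = pseudo_voigt_value(x, 0.0, 2.0, 0.01, eta)
        if eta == 1.0:
            ref = 2.0 / (1.0 + 4.0 * (x / 0.01) ** 2)
        else:
            ref = 2.0 * np.exp(-4 * math.log(2) * (x / 0.01) ** 2)
        np.testing.assert_allclose(val, ref, rtol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PseudoVoigtPeak(center=0, height=1, fwhm=-1, eta=0.5)
        with pytest.raises(ValueError):
            PseudoVoigtPeak(center=0, height=1, fwhm=1, eta=1.5)


class TestLocalBaseline:
    def test_pure_line_removed(self):
        x = make_axis((2.0, 1.0), 256)
        y = 3.0 * x - 1.0
        out, params = local_baseline(Spectrum1D(ppm_axis=x, intensity=y))
        assert np.max(np.abs(out.intensity)) < 1e-9 * np.max(np.abs(y))
        assert params[0] == pytest.approx(3.0)

    def test_peak_on_zero_baseline_unchanged(self):
        x = make_axis((1.4, 1.2), 512)
        y = _pv_on(x, 1.3, 5.0, 0.002, 0.8)
        out, _ = local_baseline(Spectrum1D(ppm_axis=x, intensity=y))
        np.testing.assert_allclose(out.intensity, y, atol=1e-3 * y.max())

    def test_short_segment_rejected(self):
        x = make_axis((1.0, 0.9), 5)
        with pytest.raises(ValueError, match="8 points"):
            local_baseline(Spectrum1D(ppm_axis=x, intensity=np.zeros(5)))


class TestSeeding:
    def test_single_peak_single_seed(self):
        x = make_axis((1.4, 1.2), 1024)
        y = _pv_on(x, 1.301, 5.0, 0.002, 1.0)
        seeds = seed_peaks_second_derivative(_segment(y))
        assert len(seeds) == 1
        assert abs(seeds[0] - 1.301) <= 2 * (0.2 / 1023)

    def test_two_peaks_separated_3w(self):
        x = make_axis((1.4, 1.2), 2048)
        w = 0.002
        y = _pv_on(x, 1.30, 4.0, w, 1.0) + _pv_on(x, 1.30 + 3 * w, 4.0, w, 1.0)
        seeds = seed_peaks_second_derivative(_segment(y))
        assert len(seeds) == 2

    def test_false_positive_rate_on_pure_noise(self):
        hits = 0
        for trial in range(40):
            rng = np.random.default_rng(1000 + trial)
            y = rng.normal(0, 1.0, 512)
            seeds = seed_peaks_second_derivative(_segment(y), prominence_k=5.0)
            hits += bool(seeds)
        assert hits <= 2  # >= 95% of trials yield zero seeds

    def test_segment_shorter_than_window_rejected(self):
        x = make_axis((1.0, 0.99), 7)
        with pytest.raises(ValueError, match="window"):
            seed_peaks_second_derivative(Spectrum1D(ppm_axis=x, intensity=np.zeros(7)))


class TestFitPeaks:
    def test_noiseless_model_recovered(self):
        x = make_axis((1.4, 1.2), 2048)
        truth = dict(center=1.3123, height=4.567, fwhm=0.0021, eta=0.8)
        y = _pv_on(x, truth["center"], truth["height"], truth["fwhm"], truth["eta"])
        res = fit_peaks(_segment(y), [truth["center"]], default_fwhm=0.002,
                        fit_baseline=False)
        assert res.converged
        p = res.peaks[0]
        assert p.center == pytest.approx(truth["center"], rel=1e-6)
        assert p.height == pytest.approx(truth["height"], rel=1e-6)
        assert p.fwhm == pytest.approx(truth["fwhm"], rel=1e-6)
        assert p.eta == pytest.approx(truth["eta"], rel=1e-4)
        assert res.residual_rms < 1e-8 * truth["height"]

    def test_overlapped_pair_areas_within_5_percent(self):
        rng = np.random.default_rng(11)
        x = make_axis((1.4, 1.2), 4096)
        w = 0.002
        c1, c2 = 1.300, 1.300 + 0.7 * w
        y = _pv_on(x, c1, 10.0, w, 0.8) + _pv_on(x, c2, 8.0, w, 0.8)
        y = y + rng.normal(0, 10.0 / 100.0, x.size)  # SNR 100
        res = fit_peaks(_segment(y), [c1, c2], default_fwhm=w)
        assert res.converged
        areas = sorted(p.area for p in res.peaks)
        t1 = pseudo_voigt_area(8.0, w, 0.8)
        t2 = pseudo_voigt_area(10.0, w, 0.8)
        assert areas[0] == pytest.approx(t1, rel=0.05)
        assert areas[1] == pytest.approx(t2, rel=0.05)

    def test_zero_seeds_rejected(self):
        x = make_axis((1.4, 1.2), 128)
        with pytest.raises(ValueError, match="seed"):
            fit_peaks(Spectrum1D(ppm_axis=x, intensity=np.zeros(128)), [])


class TestAssignment:
    def _met(self, centers, name="demo"):
        n = len(centers)
        c0 = float(np.mean(centers))
        lines = [Line(c - c0, 1.0 / n) for c in centers]
        return MetaboliteDef(
            name=name,
            multiplets=[Multiplet(center=c0, lines=lines, n_protons=1)],
            quant_region=(min(centers) - 0.01, max(centers) + 0.01),
            urine_concentration=100.0,
            calibration_concentrations=[1, 2, 3, 4, 5],
        )

    def _result(self, peaks):
        return DeconvolutionResult(peaks=peaks, baseline=(0, 0), residual_rms=0,
                                   converged=True, n_iterations=1)

    def test_match_within_tolerance(self):
        met = self._met([1.300])
        res = self._result([PseudoVoigtPeak(1.301, 2.0, 0.002, 0.8)])
        area = metabolite_area_from_fit(res, met, tolerance=0.005)
        assert area == pytest.approx(res.peaks[0].area)

    def test_no_peak_within_tolerance_is_nd(self):
        met = self._met([1.300])
        res = self._result([PseudoVoigtPeak(1.310, 2.0, 0.002, 0.8)])
        assert metabolite_area_from_fit(res, met, tolerance=0.005) is None

    def test_equidistant_tie_broken_by_larger_area(self):
        met = self._met([1.300])
        small = PseudoVoigtPeak(1.302, 1.0, 0.002, 0.8)
        big = PseudoVoigtPeak(1.298, 5.0, 0.002, 0.8)
        area = metabolite_area_from_fit(self._result([small, big]), met,
                                        tolerance=0.005)
        assert area == pytest.approx(big.area)

    def test_each_peak_used_once(self):
        met = self._met([1.300, 1.304])
        lone = PseudoVoigtPeak(1.302, 2.0, 0.002, 0.8)
        assert metabolite_area_from_fit(self._result([lone]), met,
                                        tolerance=0.005) is None

    def test_unconverged_fit_is_nd(self):
        met = self._met([1.300])
        res = DeconvolutionResult(
            peaks=[PseudoVoigtPeak(1.300, 2.0, 0.002, 0.8)],
            baseline=(0, 0), residual_rms=0, converged=False, n_iterations=1,
        )
        assert metabolite_area_from_fit(res, met) is None
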