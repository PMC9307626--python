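"""Lorentzian deconvolution: forward model, MAP fit, BIC selection, HMC."""

import numpy as np
import pytest

from tunnelfold.lineshape_fit import (
    FitResult,
    LineshapeModel,
    LorentzianPeak,
    PopulationUndefinedError,
    StatePopulations,
    fit_map,
    model_spectrum,
    populations_from_fit,
    sample_posterior,
    select_model,
)
from tunnelfold.nmr_core import AcquisitionParams, fourier_transform
from tunnelfold.synthetic_data import GroundTruthSpectrum, simulate_fid

from conftest import make_two_state_spectrum

SFO = 470.4


def ppm_axis(n=4096, center=-60.0, span=8.0):
    return np.linspace(center + span / 2, center - span / 2, n)


class TestModelSpectrum:
    def test_absorptive_dispersive_symmetry(self):
        """phi=0: real part peaks at the position, imaginary part is
        antisymmetric about it (odd point count puts the position exactly
        on a grid point)."""
        axis = ppm_axis(4097)
        model = LineshapeModel(peaks=[LorentzianPeak(-60.0, 70.0, 1.0, 0.0)])
        vals = model_spectrum(model, axis, SFO)
        i0 = np.argmax(vals.real)
        assert axis[i0] == pytest.approx(-60.0, abs=abs(axis[1] - axis[0]))
        # antisymmetry of the dispersive part around the peak
        k = 500
        left = vals.imag[i0 - k: i0][::-1]
        right = vals.imag[i0 + 1: i0 + 1 + k]
        np.testing.assert_allclose(left, -right, atol=1e-4 * np.abs(vals.real).max())

    def test_area_by_trapezoidal_integration(self):
        """Integrating the absorptive part over a wide window recovers the
        area within 1 %."""
        fwhm = 70.0
        span_ppm = 2 * 50 * fwhm / SFO  # +/- 50 FWHM
        axis = np.linspace(-60 + span_ppm / 2, -60 - span_ppm / 2, 2**16)
        model = LineshapeModel(peaks=[LorentzianPeak(-60.0, fwhm, 2.5, 0.0)])
        vals = model_spectrum(model, axis, SFO)
        dnu = abs(axis[1] - axis[0]) * SFO
        assert np.trapezoid(vals.real[::-1], dx=dnu) == pytest.approx(2.5, rel=0.01)

    def test_empty_model_constant_baseline(self):
        axis = ppm_axis(256)
        model = LineshapeModel(baseline_coeffs=np.array([1.5 - 0.5j]))
        vals = model_spectrum(model, axis, SFO)
        np.testing.assert_allclose(vals, 1.5 - 0.5j)

    def test_fwhm_parameterization(self):
        """The real part drops to half max at +/- FWHM/2."""
        fwhm = 100.0
        axis = ppm_axis(2**15, span=4.0)
        model = LineshapeModel(peaks=[LorentzianPeak(-60.0, fwhm, 1.0, 0.0)])
        vals = model_spectrum(model, axis, SFO).real
        half = vals.max() / 2
        above = axis[vals >= half]
        width_hz = (above.max() - above.min()) * SFO
        assert width_hz == pytest.approx(fwhm, rel=0.01)


class TestFitMap:
    def test_noiseless_round_trip(self, acq_4k):
        """Fitting the FT of a noiseless synthetic recovers the generating
        parameters to high precision (time/frequency equivalence)."""
        truth, spec = make_two_state_spectrum(0.59, acq_4k, snr=None)
        fit = fit_map(spec, n_peaks=2, degree=0)
        by_pos = sorted(
            zip(fit.map_params[0::4][:2], fit.map_params[1::4][:2], fit.map_params[2::4][:2])
        )
        truth_sorted = sorted((p, w, a) for p, w, a, _ in truth.peaks)
        for (pos, fwhm, area), (tp, tw, ta) in zip(by_pos, truth_sorted):
            assert pos == pytest.approx(tp, abs=1e-5)
            assert fwhm == pytest.approx(tw, rel=1e-4)
            assert area == pytest.approx(ta, rel=1e-4)

    def test_reduced_chi_square_near_unity(self, acq_8k):
        truth, spec = make_two_state_spectrum(0.59, acq_8k, snr=20, seed=42)
        fit = fit_map(spec, n_peaks=2, degree=1)
        n = 2 * spec.axis.size
        chi2 = -2 * (fit.log_likelihood_max + n * np.log(fit.noise_sd * np.sqrt(2 * np.pi)))
        assert 0.8 < chi2 / n < 1.2

    def test_init_at_truth_converges(self, acq_4k):
        truth, spec = make_two_state_spectrum(0.4, acq_4k, snr=30, seed=2)
        init = LineshapeModel(
            peaks=[LorentzianPeak(p, w, a, ph) for p, w, a, ph in truth.peaks]
        )
        fit = fit_map(spec, n_peaks=2, degree=-1, init=init)
        pops = populations_from_fit(fit)
        assert pops.p_f == pytest.approx(0.4, abs=0.02)

    def test_degenerate_positions_flagged(self, acq_4k):
        truth = GroundTruthSpectrum(
            peaks=[(-60.0, 80.0, 0.5, 0.0), (-60.0, 80.0, 0.5, 0.0)], noise_sd=0.0
        )
        spec = fourier_transform(simulate_fid(truth, acq_4k), zero_fill_factor=1)
        spec.noise_sd = 1e-8
        init = LineshapeModel(
            peaks=[LorentzianPeak(-60.0005, 80.0, 0.5, 0.0), LorentzianPeak(-59.9995, 80.0, 0.5, 0.0)]
        )
        fit = fit_map(spec, n_peaks=2, degree=-1, init=init)
        assert any("degenerate" in w for w in fit.warnings)


class TestSelectModel:
    def test_single_peak_preferred_on_single_peak_data(self, acq_4k):
        truth = GroundTruthSpectrum(peaks=[(-60.0, 80.0, 1.0, 0.0)], noise_sd=0.001, seed=3)
        spec = fourier_transform(simulate_fid(truth, acq_4k), zero_fill_factor=1)
        from tunnelfold.nmr_core import estimate_noise

        spec.noise_sd = estimate_noise(spec, exclusion_windows=[(-61.5, -58.5)])
        fit = select_model(spec, [(1, 0, False), (2, 0, False)])
        assert len(fit.map_model.peaks) == 1

    def test_two_peaks_win_at_realistic_snr(self, acq_4k):
        _, spec = make_two_state_spectrum(0.59, acq_4k, snr=20, seed=4)
        fit = select_model(spec, [(1, 0, False), (2, 0, False)])
        assert len(fit.map_model.peaks) == 2

    def test_selection_order_invariant(self, acq_4k):
        _, spec = make_two_state_spectrum(0.59, acq_4k, snr=20, seed=4)
        a = select_model(spec, [(1, 0, False), (2, 0, False)])
        b = select_model(spec, [(2, 0, False), (1, 0, False)])
        assert len(a.map_model.peaks) == len(b.map_model.peaks)
        assert a.bic == b.bic

    def test_empty_candidates_rejected(self, acq_4k):
        _, spec = make_two_state_spectrum(0.5, acq_4k, snr=20)
        with pytest.raises(ValueError):
            select_model(spec, [])

    @pytest.mark.parametrize("n_points", [1024, 2048, 4096])
    def test_bic_consistency_across_sizes(self, n_points):
        """The true two-peak model is selected at every spectrum size."""
        acq = AcquisitionParams(n_points=n_points, dwell=0.350 / n_points)
        _, spec = make_two_state_spectrum(0.59, acq, snr=20, seed=6)
        fit = select_model(spec, [(1, 0, False), (2, 0, False)])
        assert len(fit.map_model.peaks) == 2


class TestSamplePosterior:
    @pytest.fixture(scope="class")
    def hmc_fit(self):
        acq = AcquisitionParams(n_points=2048, dwell=0.350 / 2048)
        truth, spec = make_two_state_spectrum(0.59, acq, snr=20, seed=10)
        fit0 = fit_map(spec, n_peaks=2, degree=1)
        fit = sample_posterior(spec, fit0, n_chains=2, n_warmup=250, n_draws=250, seed=11)
        return truth, fit

    def test_posterior_means_near_truth(self, hmc_fit):
        """Every parameter's posterior mean lies within 3 posterior sd of
        the generating value."""
        truth, fit = hmc_fit
        flat = fit.posterior.reshape(-1, fit.posterior.shape[-1])
        names = fit.param_names
        # map truth peaks (sorted by position) onto fitted peak indices
        fitted_pos = [flat[:, names.index(f"peak{i}_position")].mean() for i in range(2)]
        order = np.argsort(fitted_pos)
        truth_sorted = sorted(truth.peaks)
        for rank, i in enumerate(order):
            tp, tw, ta, tph = truth_sorted[rank]
            for suffix, target in (("position", tp), ("fwhm", tw), ("area", ta)):
                col = flat[:, names.index(f"peak{i}_{suffix}")]
                assert abs(col.mean() - target) < 3 * col.std() + 1e-9, (suffix, target)

    def test_rhat_close_to_one(self, hmc_fit):
        _, fit = hmc_fit
        assert max(fit.rhat.values()) < 1.05

    def test_same_seed_identical_draws(self):
        acq = AcquisitionParams(n_points=1024, dwell=0.350 / 1024)
        _, spec = make_two_state_spectrum(0.5, acq, snr=20, seed=12)
        fit0 = fit_map(spec, n_peaks=2, degree=0)
        a = sample_posterior(spec, fit0, n_chains=1, n_warmup=50, n_draws=50, seed=5)
        b = sample_posterior(spec, fit0, n_chains=1, n_warmup=50, n_draws=50, seed=5)
        np.testing.assert_array_equal(a.posterior, b.posterior)

    def test_population_invariant_to_global_phase(self, acq_4k):
        """Rotating the whole spectrum by a global phase does not move the
        recovered populations when phases are free parameters."""
        truth, spec = make_two_state_spectrum(0.41, acq_4k, snr=50, seed=13)
        fit0 = fit_map(spec, n_peaks=2, degree=0)
        p0 = populations_from_fit(fit0).p_f
        spec.values = spec.values * np.exp(1j * 0.6)
        fit1 = fit_map(spec, n_peaks=2, degree=0)
        p1 = populations_from_fit(fit1).p_f
        assert p1 == pytest.approx(p0, abs=0.01)


class TestPopulations:
    def make_fit(self, areas, positions=(-60.4, -59.6), broad_area=0.0):
        peaks = [LorentzianPeak(p, 80.0, a, 0.0) for p, a in zip(positions, areas)]
        broad = LorentzianPeak(-60.0, 1000.0, broad_area, 0.0) if broad_area else None
        model = LineshapeModel(peaks=peaks, broad=broad)
        from tunnelfold.lineshape_fit import _layout_of, _pack_model

        return FitResult(
            map_model=model, log_likelihood_max=0.0, bic=0.0, noise_sd=1.0,
            n_points=0, param_names=_layout_of(model).names(),
            map_params=_pack_model(model),
        )

    def test_ratio_definition(self):
        pops = populations_from_fit(self.make_fit([41.0, 59.0]))
        assert pops.p_f == pytest.approx(0.59, abs=1e-12)

    def test_broad_component_excluded(self):
        pops = populations_from_fit(self.make_fit([1.0, 1.0], broad_area=5.0))
        assert pops.p_f == pytest.approx(0.5, abs=1e-12)

    def test_reference_shift_labeling(self):
        """With explicit reference shifts, labels follow proximity, not
        position ordering."""
        pops = populations_from_fit(
            self.make_fit([30.0, 70.0]), ref_shifts=(-59.6, -60.4)
        )
        # now F reference is upfield: the upfield peak area (30) is F
        assert pops.p_f == pytest.approx(0.30, abs=1e-12)

    def test_single_peak_routes_to_detection_bound(self):
        with pytest.raises(PopulationUndefinedError):
            populations_from_fit(self.make_fit([1.0], positions=(-60.4,)))

    def test_population_sum_invariant(self):
        with pytest.raises(ValueError):
            StatePopulations(p_f=0.6, p_u=0.5, sd_pf=0.0)
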