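import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import filmrheo as fr
from filmrheo.errors import InsufficientResolutionError, RangeError
from filmrheo.rheology_spectrum import ViscoelasticSpectrum
from filmrheo.transients_io import RelaxationTransient

GRID = fr.default_frequency_grid()


def debye(amp, tau, strain, freqs):
    """Closed-form single Maxwell element, for independent checking."""
    wt = 2 * np.pi * np.asarray(freqs) * tau
    return (amp / strain) * wt ** 2 / (1 + wt ** 2), (amp / strain) * wt / (1 + wt ** 2)


class TestAnalyticSpectrum:
    def test_single_element_peak_location_and_height(self):
        amp, tau, strain = 10.0, 100.0, 0.05
        freqs = np.geomspace(1e-5, 1e-1, 4000)
        spec = fr.analytic_spectrum([(amp, tau)], 0.0, strain, freqs)
        ipk = np.argmax(spec.e_imag)
        assert spec.freq[ipk] == pytest.approx(1 / (2 * np.pi * tau), rel=1e-3)
        assert spec.e_imag[ipk] == pytest.approx((amp / strain) / 2, rel=1e-6)

    def test_plateau_only_constant(self):
        spec = fr.analytic_spectrum([], 3.0, 0.05, GRID)
        np.testing.assert_allclose(spec.e_real, 60.0)
        np.testing.assert_allclose(spec.e_imag, 0.0)

    def test_frequency_limits(self):
        comps, plateau, strain = [(4.0, 20.0), (6.0, 2000.0)], 2.0, 0.05
        lo = fr.analytic_spectrum(comps, plateau, strain, np.array([1e-9]))
        hi = fr.analytic_spectrum(comps, plateau, strain, np.array([1e6]))
        assert lo.e_real[0] == pytest.approx(plateau / strain, rel=1e-4)
        assert hi.e_real[0] == pytest.approx((plateau + 10.0) / strain, rel=1e-4)

    def test_matches_independent_debye_form(self):
        er, ei = debye(7.0, 300.0, 0.05, GRID)
        spec = fr.analytic_spectrum([(7.0, 300.0)], 0.0, 0.05, GRID)
        np.testing.assert_allclose(spec.e_real, er, rtol=1e-12)
        np.testing.assert_allclose(spec.e_imag, ei, rtol=1e-12)

    @given(st.lists(st.tuples(st.floats(0.1, 20), st.floats(1.0, 1e4)),
                    min_size=1, max_size=4))
    def test_passivity_and_monotonicity(self, comps):
        """For nonnegative amplitudes E_IM >= 0 and E_R is non-decreasing."""
        spec = fr.analytic_spectrum(comps, 1.0, 0.05, GRID)
        assert np.all(spec.e_imag >= 0)
        assert np.all(np.diff(spec.e_real) >= -1e-9 * np.abs(spec.e_real[:-1]))

    def test_linearity_in_amplitudes(self):
        comps = [(3.0, 15.0), (5.0, 800.0)]
        one = fr.analytic_spectrum(comps, 2.0, 0.05, GRID)
        two = fr.analytic_spectrum([(2 * a, tau) for a, tau in comps], 4.0,
                                   0.05, GRID)
        np.testing.assert_allclose(two.e_real, 2 * one.e_real, rtol=1e-12)
        np.testing.assert_allclose(two.e_imag, 2 * one.e_imag, rtol=1e-12)

    def test_eta_d_recovers_dilatational_viscosity(self):
        spec = fr.analytic_spectrum([(10.0, 100.0)], 0.0, 0.05, GRID)
        np.testing.assert_allclose(spec.eta_d * 2 * np.pi * spec.freq,
                                   spec.e_imag, rtol=1e-12)


class TestComputeSpectrum:
    def test_single_exponential_within_one_percent(self, single_exp_transient):
        freqs = np.geomspace(1.6e-4, 1.6e-2, 100)
        spec = fr.compute_spectrum(single_exp_transient, freqs)
        oracle = fr.analytic_spectrum([(10.0, 100.0)], 0.0, 0.05, freqs)
        np.testing.assert_allclose(spec.e_real, oracle.e_real, rtol=0.01)
        np.testing.assert_allclose(spec.e_imag, oracle.e_imag, rtol=0.01)

    @pytest.mark.parametrize("comps,plateau", [
        ([(10.0, 100.0)], 0.0),
        ([(5.0, 10.0), (5.0, 1000.0)], 2.0),
        ([(3.0, 5.0), (4.0, 150.0), (5.0, 4000.0)], 1.5),
    ])
    def test_oracle_equivalence_multi_component(self, comps, plateau):
        """Numerical transform of noiseless Eq-style transients agrees with
        the closed form within 1% over the resolvable band."""
        tau_max = max(tau for _, tau in comps)
        t = fr.gen_relaxation(comps, plateau, strain=0.05,
                              sampling=(1.0, 10 * tau_max))
        lo, hi = fr.resolvable_band(t)
        freqs = np.geomspace(max(lo * 10, 1.6e-4), min(hi / 10, 1.6e-2), 60)
        spec = fr.compute_spectrum(t, freqs)
        oracle = fr.analytic_spectrum(comps, plateau, 0.05, freqs)
        np.testing.assert_allclose(spec.e_real, oracle.e_real, rtol=0.01)
        np.testing.assert_allclose(spec.e_imag, oracle.e_imag, rtol=0.01,
                                   atol=1e-3)

    def test_zero_response_gives_zero_spectrum(self):
        t = RelaxationTransient(time=np.arange(0.0, 200.0),
                                pi=np.full(200, 18.0), pi0=18.0, strain=0.05)
        spec = fr.compute_spectrum(t, np.geomspace(1e-3, 0.4, 20))
        np.testing.assert_allclose(spec.e_real, 0.0, atol=1e-12)
        np.testing.assert_allclose(spec.e_imag, 0.0, atol=1e-12)

    def test_pure_plateau_analytic_term(self):
        time = np.arange(0.0, 200.0)
        t = RelaxationTransient(time=time, pi=18.0 + np.full(200, 4.0),
                                pi0=18.0, strain=0.05)
        spec = fr.compute_spectrum(t, np.geomspace(1e-3, 0.4, 20))
        np.testing.assert_allclose(spec.e_real, 4.0 / 0.05, rtol=1e-12)
        np.testing.assert_allclose(spec.e_imag, 0.0, atol=1e-9)
        assert spec.meta["plateau"] == pytest.approx(4.0)

    def test_low_frequency_limit_is_equilibrium_elasticity(self):
        t = fr.gen_relaxation([(6.0, 20.0)], plateau=3.0, strain=0.05,
                              sampling=(0.5, 2000.0))
        spec = fr.compute_spectrum(t, np.array([1.0 / (10 * 1999.5)]),
                                   plateau=3.0)
        assert spec.e_real[0] == pytest.approx(3.0 / 0.05, rel=0.02)

    def test_out_of_band_frequencies_rejected(self, single_exp_transient):
        with pytest.raises(RangeError):
            fr.compute_spectrum(single_exp_transient, np.array([1e-6]))
        with pytest.raises(RangeError):
            fr.compute_spectrum(single_exp_transient, np.array([10.0]))

    def test_irregular_sampling_supported(self):
        rng = np.random.default_rng(0)
        time = np.sort(rng.uniform(0, 1000.0, 1500))
        time[0] = 0.0
        pi = 18.0 + 10.0 * np.exp(-time / 100.0)
        t = RelaxationTransient(time=time, pi=pi, pi0=18.0, strain=0.05)
        freqs = np.geomspace(3e-4, 5e-3, 30)
        spec = fr.compute_spectrum(t, freqs)
        oracle = fr.analytic_spectrum([(10.0, 100.0)], 0.0, 0.05, freqs)
        np.testing.assert_allclose(spec.e_real, oracle.e_real, rtol=0.02)
        np.testing.assert_allclose(spec.e_imag, oracle.e_imag, rtol=0.02)


class TestColeCole:
    def test_single_element_one_peak(self):
        spec = fr.analytic_spectrum([(10.0, 100.0)], 0.0, 0.05, GRID)
        assert fr.cole_cole(spec).peaks.count == 1

    def test_two_separated_elements_two_peaks(self):
        spec = fr.analytic_spectrum([(5.0, 10.0), (5.0, 1000.0)], 0.0, 0.05,
                                    fr.default_frequency_grid(1e-5, 1.0))
        cc = fr.cole_cole(spec)
        assert cc.peaks.count == 2
        f1, f2 = cc.peaks.peaks[0][0], cc.peaks.peaks[1][0]
        assert f1 < f2  # ordered by frequency

    def test_flat_spectrum_zero_peaks(self):
        spec = fr.analytic_spectrum([], 3.0, 0.05, GRID)
        assert fr.cole_cole(spec).peaks.count == 0

    def test_short_spectrum_rejected(self):
        spec = ViscoelasticSpectrum(freq=[1e-3, 2e-3, 3e-3],
                                    e_real=[1, 2, 3], e_imag=[0.1, 0.2, 0.1],
                                    strain=0.05)
        with pytest.raises(InsufficientResolutionError):
            fr.cole_cole(spec)

    def test_semicircle_analytic(self):
        """A single Maxwell element's Cole-Cole curve is the semicircle of
        radius E/2 centered at (E/2, 0)."""
        amp, strain = 10.0, 0.05
        spec = fr.analytic_spectrum([(amp, 100.0)], 0.0, strain,
                                    fr.default_frequency_grid(1e-5, 1.0, 100))
        e = amp / strain
        radius = np.hypot(spec.e_real - e / 2, spec.e_imag)
        np.testing.assert_allclose(radius, e / 2, rtol=1e-6)

    def test_semicircle_numerical_pipeline(self, single_exp_transient):
        freqs = np.geomspace(1.6e-4, 1.6e-2, 80)
        spec = fr.compute_spectrum(single_exp_transient, freqs)
        e = 10.0 / 0.05
        radius = np.hypot(spec.e_real - e / 2, spec.e_imag)
        np.testing.assert_allclose(radius, e / 2, rtol=0.02)


class TestClassifyFilm:
    def test_plateau_only_is_elastic(self):
        spec = fr.analytic_spectrum([], 3.0, 0.05, GRID)
        verdict = fr.classify_film(spec, (1e-4, 1e-3))
        assert verdict.label == "predominantly_elastic"
        assert verdict.elastic_fraction == 1.0

    def test_narrow_band_at_crossover_is_mixed(self):
        """At the E_IM peak of a plateau-free element, E_R = E_IM exactly."""
        tau = 100.0
        nu_peak = 1 / (2 * np.pi * tau)
        freqs = np.geomspace(nu_peak / 1.3, nu_peak * 1.3, 51)
        spec = fr.analytic_spectrum([(10.0, tau)], 0.0, 0.05, freqs)
        verdict = fr.classify_film(spec, (freqs[0], freqs[-1]))
        assert verdict.label == "mixed"
        assert 0.1 < verdict.elastic_fraction < 0.9

    def test_mgs_like_film_predominantly_elastic(self):
        """A meibum-like spectrum (large equilibrium plateau) keeps the
        storage modulus above the loss modulus across the low band."""
        p = fr.mgs_relaxation_preset()
        t = fr.gen_relaxation(**p)
        spec = fr.compute_spectrum(t)
        verdict = fr.classify_film(spec, (1e-4, 1e-3))
        assert verdict.label == "predominantly_elastic"

    def test_empty_band_rejected(self):
        spec = fr.analytic_spectrum([(1.0, 10.0)], 0.0, 0.05, GRID)
        with pytest.raises(RangeError):
            fr.classify_film(spec, (2.0, 3.0))
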