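"""Noise theory: binomial current noise, the multi-Lorentzian spectra checked
against the explicit four- and seven-term closed forms, quasi-active vs
sine-injection impedance, and the filtered voltage-noise quantities."""

import math

import numpy as np
import pytest

import channelnoise.kinetics as K
import channelnoise.noise_theory as NT
import channelnoise.simulator as S
from channelnoise.simulator import Population


V0 = -65.0
AREA = 1000.0


@pytest.fixture(scope="module")
def pops(hh1000):
    return {p.scheme.name: p for p in hh1000.populations}


@pytest.fixture(scope="module")
def Z_hh(hh1000):
    return NT.quasi_active_impedance(hh1000, V0)


def gate_stats(gate):
    rp = K._HH_RATES[gate]
    return K.steady_state(rp, V0), K.time_constant(rp, V0)


class TestBinomialNoise:
    def test_na_to_k_current_sd_ratio(self, pops):
        """The Na+/K+ current-noise s.d. ratio at rest is ~1.6-1.7."""
        _, _, s_na = NT.binomial_noise(pops["hh_na"], AREA, V0)
        _, _, s_k = NT.binomial_noise(pops["hh_k"], AREA, V0)
        assert s_na / s_k == pytest.approx(1.64, abs=0.08)

    def test_zero_at_reversal(self, pops):
        _, _, s = NT.binomial_noise(pops["hh_k"], AREA, -77.0)
        assert s == 0.0

    def test_moments(self, pops):
        mean, var, s = NT.binomial_noise(pops["hh_k"], AREA, V0)
        p = K.open_probability(K.get_scheme("hh_k"), V0)
        assert mean == pytest.approx(18000 * p, rel=1e-12)
        assert var == pytest.approx(18000 * p * (1 - p), rel=1e-12)


def k_spectrum_closed_form(f, N, i, n, tau):
    """Printed four-Lorentzian K+ spectrum (tau in ms -> seconds internally)."""
    w = 2 * math.pi * np.asarray(f)
    t = tau * 1e-3
    bracket = ((1 - n) ** 4 * 4 / (16 + w ** 2 * t ** 2)
               + n * (1 - n) ** 3 * 12 / (9 + w ** 2 * t ** 2)
               + n ** 2 * (1 - n) ** 2 * 12 / (4 + w ** 2 * t ** 2)
               + n ** 3 * (1 - n) * 4 / (1 + w ** 2 * t ** 2))
    return 4 * N * n ** 4 * i ** 2 * t * bracket


def na_spectrum_closed_form(f, N, i, m, h, tau_m, tau_h):
    """Printed seven-Lorentzian Na+ spectrum."""
    w = 2 * math.pi * np.asarray(f)
    tm, th = tau_m * 1e-3, tau_h * 1e-3
    rm, rh = (1 - m) / m, (1 - h) / h
    t1 = tm * th / (tm + th)
    t2 = tm * th / (tm + 2 * th)
    t3 = tm * th / (tm + 3 * th)
    bracket = (rm * 3 * tm / (1 + w ** 2 * tm ** 2)
               + rm ** 2 * 6 * tm / (4 + w ** 2 * tm ** 2)
               + rm ** 3 * 3 * tm / (9 + w ** 2 * tm ** 2)
               + rh * th / (1 + w ** 2 * th ** 2)
               + 3 * rh * rm * t1 / (1 + (w * t1) ** 2)
               + 3 * rh * rm ** 2 * t2 / (1 + (w * t2) ** 2)
               + rh * rm ** 3 * t3 / (1 + (w * t3) ** 2))
    return 4 * N * i ** 2 * (m ** 3 * h) ** 2 * bracket


class TestCurrentSpectra:
    def test_k_has_four_terms_matching_closed_form(self, pops):
        spec = NT.current_psd(pops["hh_k"], AREA, V0)
        assert len(spec.terms) == 4
        n, tau = gate_stats("n")
        f = np.logspace(-1, 5, 200)
        expected = k_spectrum_closed_form(f, 18000, 20e-3 * (V0 + 77.0), n, tau)
        assert np.allclose(spec(f), expected, rtol=1e-10)
        # corner frequencies are k/(2 pi tau_n), k = 1..4
        got = sorted(fc for _, fc in spec.terms)
        want = sorted(k / (2 * math.pi * tau * 1e-3) for k in (1, 2, 3, 4))
        assert np.allclose(got, want, rtol=1e-12)

    def test_na_has_seven_terms_matching_closed_form(self, pops):
        spec = NT.current_psd(pops["hh_na"], AREA, V0)
        assert len(spec.terms) == 7
        m, tau_m = gate_stats("m")
        h, tau_h = gate_stats("h")
        f = np.logspace(-1, 5, 200)
        expected = na_spectrum_closed_form(f, 60000, 20e-3 * (V0 - 50.0), m, h,
                                           tau_m, tau_h)
        assert np.allclose(spec(f), expected, rtol=1e-10)

    def test_dominant_corners(self, pops):
        """K+ ~115 Hz (4/2pi tau_n); Na+ ~1980 Hz (3/2pi tau_m)."""
        assert NT.current_psd(pops["hh_k"], AREA, V0).dominant_corner() == \
            pytest.approx(115.0, rel=0.05)
        assert NT.current_psd(pops["hh_na"], AREA, V0).dominant_corner() == \
            pytest.approx(1980.0, rel=0.05)

    @pytest.mark.parametrize("name", ["hh_k", "hh_na", "ca1_na", "ca1_kdr", "ca1_ka"])
    @pytest.mark.parametrize("V", [-80.0, -65.0, -50.0, -30.0])
    def test_integral_equals_binomial_variance(self, name, V):
        """Conservation between the spectral expansion and the binomial model:
        integral of S_I over f >= 0 equals i^2 N p (1-p) to 1e-10 relative."""
        pop = Population(K.get_scheme(name), density=20.0)
        spec = NT.current_psd(pop, AREA, V)
        _, var_count, sigma_I = NT.binomial_noise(pop, AREA, V)
        assert spec.variance() == pytest.approx(sigma_I ** 2, rel=1e-10)

    def test_spectrum_is_non_increasing(self, pops):
        f = np.logspace(-1, 5, 400)
        for name in ("hh_k", "hh_na"):
            Sf = NT.current_psd(pops[name], AREA, V0)(f)
            assert np.all(np.diff(Sf) <= 1e-15)

    def test_monotonicity_with_channel_count(self, pops):
        small = NT.current_psd(pops["hh_k"], 100.0, V0).variance()
        big = NT.current_psd(pops["hh_k"], 1000.0, V0).variance()
        assert big == pytest.approx(10 * small, rel=1e-9)


class TestImpedance:
    def test_passive_closed_form(self):
        m = S.MembraneModel(c_m=1.0, area=1000.0, populations=(), leaks=((3.0, -55.0),))
        R = 1e3 / m.g_leak_nS  # MOhm
        C = m.capacitance_pF
        f = np.logspace(-1, 5, 121)
        Z = NT.quasi_active_impedance(m, -55.0, f)
        expected = R / np.sqrt(1.0 + (2 * math.pi * f * R * C * 1e-6) ** 2)
        assert np.allclose(Z.magnitude(), expected, rtol=1e-10)

    def test_hh_resonance(self, Z_hh):
        """Active gating makes |Z| resonate around 1e2 Hz, well above |Z(0)|."""
        mag = Z_hh.magnitude()
        fpk = Z_hh.freqs[np.argmax(mag)]
        assert 30.0 < fpk < 200.0
        assert mag.max() > 1.5 * mag[0]

    def test_quasi_active_matches_sine_injection(self, hh1000, hh_rest):
        """Cross-validation of the linearization against the measured
        transfer function of the deterministic model (within 2%)."""
        freqs = np.array([10.0, 50.0, 100.0, 500.0, 2000.0])
        Zq = NT.quasi_active_impedance(hh1000, hh_rest, freqs)
        Ze = NT.empirical_impedance(hh1000, hh_rest, freqs, amplitude=1.0)
        assert np.allclose(Ze.magnitude(), Zq.magnitude(), rtol=0.02)

    def test_capacitive_asymptote(self, hh1000, hh_rest):
        f = 5000.0
        Ze = NT.empirical_impedance(hh1000, hh_rest, [f], amplitude=2.0)
        expected = 1e3 / (2 * math.pi * f * hh1000.capacitance_pF * 1e-3)  # MOhm
        assert Ze.magnitude()[0] == pytest.approx(expected, rel=0.05)

    def test_amplitude_too_large_raises(self, hh1000, hh_rest):
        with pytest.raises(NT.AmplitudeTooLargeError):
            NT.empirical_impedance(hh1000, hh_rest, [20.0], amplitude=100.0)


class TestVoltageNoise:
    def test_unit_impedance_identity(self, pops):
        spec = NT.current_psd(pops["hh_k"], AREA, V0)
        f = NT.default_freq_grid()
        Z = NT.ImpedanceSpectrum(freqs=f, Z=np.ones_like(f, dtype=complex))
        _, S_V = NT.voltage_psd(spec, Z)
        assert np.allclose(S_V, spec(f) * 1e-6, rtol=1e-12)

    def test_grid_mismatch_raises(self):
        f = NT.default_freq_grid()
        Z = NT.ImpedanceSpectrum(freqs=f, Z=np.ones_like(f, dtype=complex))
        with pytest.raises(NT.GridError):
            NT.voltage_psd(np.ones(10), Z)

    def test_single_lorentzian_variance_closed_form(self):
        a, fc = 2.5, 40.0
        spec = NT.LorentzianSum(terms=[(a, fc)])
        f = NT.default_freq_grid(1e-2, 1e5)
        Z = NT.ImpedanceSpectrum(freqs=f, Z=3.0 * np.ones_like(f, dtype=complex))
        _, S_V = NT.voltage_psd(spec, Z)
        expected = a * fc * math.pi / 2 * 9.0 * 1e-6
        assert NT.voltage_variance(f, S_V) == pytest.approx(expected, rel=1e-3)

    def test_non_decaying_spectrum_raises(self):
        f = NT.default_freq_grid()
        with pytest.raises(NT.GridError):
            NT.voltage_variance(f, np.ones_like(f))

    def test_k_contributes_several_times_na_voltage_variance(self, hh1000, Z_hh, pops):
        """K+ fluctuations contribute ~4x the Na+ voltage-noise variance."""
        var = {}
        for name in ("hh_k", "hh_na"):
            _, S_V = NT.voltage_psd(NT.current_psd(pops[name], AREA, V0), Z_hh)
            var[name] = NT.voltage_variance(Z_hh.freqs, S_V)
        ratio = var["hh_k"] / var["hh_na"]
        assert 3.2 < ratio < 4.5
        share = ratio / (1 + ratio)
        assert 0.70 < share < 0.85  # "~75%" of the summed membrane noise

    def test_filter_ratios_match_reported_values(self, hh1000, Z_hh, pops):
        """r_Na ~44.5 MOhm, r_K ~141.7 MOhm at rest, 1000 um^2."""
        r_na = NT.filter_ratio(pops["hh_na"], hh1000, V0, Z=Z_hh).r
        r_k = NT.filter_ratio(pops["hh_k"], hh1000, V0, Z=Z_hh).r
        assert r_na == pytest.approx(44.5, rel=0.05)
        assert r_k == pytest.approx(141.7, rel=0.05)
        assert r_k > r_na  # slow noise is filtered less

    def test_r_decreases_with_source_corner_frequency(self):
        """Through a low-pass (non-resonant) membrane, faster noise sources
        (higher corner) are attenuated more: r is monotone non-increasing in
        f_c. (A resonant filter breaks this locally -- that is exactly the
        non-monotonicity of the impedance factor z(tau).)"""
        m = S.MembraneModel(c_m=1.0, area=1000.0, populations=(), leaks=((3.0, -55.0),))
        f = NT.default_freq_grid(1e-3, 1e6)
        Z = NT.quasi_active_impedance(m, -55.0, f)
        rs = []
        for fc in (1.0, 10.0, 100.0, 1000.0):
            spec = NT.LorentzianSum(terms=[(1.0 / fc, fc)])
            _, S_V = NT.voltage_psd(spec, Z)
            sigma_V = math.sqrt(NT.voltage_variance(f, S_V))
            sigma_I = math.sqrt(spec.variance())
            rs.append(sigma_V / sigma_I / 1e-3)
        assert rs[0] > rs[1] > rs[2] > rs[3]

    def test_white_noise_through_rc_closed_form(self):
        """OU-through-RC has variance R^2 tau/(tau+RC): check the spectral
        pipeline against the analytic integral."""
        m = S.MembraneModel(c_m=1.0, area=1000.0, populations=(), leaks=((3.0, -55.0),))
        R = 1e3 / m.g_leak_nS  # MOhm
        RC = m.capacitance_pF / m.g_leak_nS  # ms
        f = NT.default_freq_grid(1e-3, 1e6)
        Z = NT.quasi_active_impedance(m, -55.0, f)
        for tau in (0.5, 5.0, 50.0):
            fc = 1e3 / (2 * math.pi * tau)
            spec = NT.LorentzianSum(terms=[(4.0 * tau * 1e-3, fc)])  # unit variance
            _, S_V = NT.voltage_psd(spec, Z)
            got = NT.voltage_variance(f, S_V)
            expected = R ** 2 * tau / (tau + RC) * 1e-6  # mV^2 per unit pA^2
            assert got == pytest.approx(expected, rel=5e-3)


class TestNoiseReport:
    def test_report_contains_five_factor_decomposition(self, hh1000):
        df = NT.noise_report(hh1000, V0)
        for col in ("p_open", "N", "driving_force_mV", "sigma_I_pA",
                    "dominant_fc_Hz", "sigma_V_mV", "r_MOhm", "variance_share"):
            assert col in df.columns
        assert df["variance_share"].sum() == pytest.approx(1.0, rel=1e-9)
        k = df.set_index("population")
        assert k.loc["hh_k", "variance_share"] > k.loc["hh_na", "variance_share"]
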