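"""Analytic channel-noise layer: binomial steady-state noise, Lorentzian
current-noise spectra, quasi-active membrane impedance, and the resulting
voltage-noise spectra and variances.

At a fixed voltage each channel population's open-count is binomial,
``var = N p (1-p)``, and its current autocovariance is a sum of decaying
exponentials obtained from the multinomial expansion of

    prod_j (x_j_inf + (1 - x_j_inf) e^(-t/tau_j))^mult_j  -  (open prob)^2

so the one-sided power spectral density is a finite sum of Lorentzians
``S(f) = sum_k a_k / (1 + (f/f_c_k)^2)`` (four terms for a single
four-gate activation scheme, seven for a three-plus-one activation/
inactivation scheme). Spectral densities use the one-sided convention
``integral_0^inf S(f) df = variance``, i.e. a single two-state population
has ``S(0) = 4 N i^2 p (1-p) tau``.

Voltage noise follows from the generalized Ohm's law
``S_V(f) = S_I(f) |Z(f)|^2`` with Z the membrane impedance, linearized
around the operating point (quasi-active membrane) or measured by sine
injection into the deterministic model.

Units: f in Hz, S_I in pA^2/Hz, Z in MOhm, S_V in mV^2/Hz
(1 pA * 1 MOhm = 1e-3 mV).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import (
    ChannelScheme,
    UnsupportedSchemeError,
    steady_state,
    steady_state_derivative,
    time_constant,
    open_probability,
)
from .simulator import MembraneModel, Population, integrate_deterministic, with_modes

__all__ = [
    "LorentzianSum",
    "ImpedanceSpectrum",
    "NoiseSummary",
    "ImpedanceDivergenceError",
    "AmplitudeTooLargeError",
    "GridError",
    "binomial_noise",
    "current_psd",
    "quasi_active_impedance",
    "quasi_active_admittance",
    "empirical_impedance",
    "voltage_psd",
    "voltage_variance",
    "filter_ratio",
    "noise_report",
    "default_freq_grid",
]

PA_MOHM_TO_MV = 1e-3  # 1 pA through 1 MOhm = 1e-3 mV


class ImpedanceDivergenceError(RuntimeError):
    """Quasi-active admittance vanishes at some frequency (divergent impedance);
    use empirical_impedance instead."""


class AmplitudeTooLargeError(RuntimeError):
    """Sine-injection response is outside the linear regime."""


class GridError(ValueError):
    """Frequency grids do not match, or the grid is too short for the integral."""


def default_freq_grid(f_lo: float = 1e-1, f_hi: float = 1e5, per_decade: int = 60) -> np.ndarray:
    """Logarithmic frequency grid in Hz (default 0.1 Hz - 100 kHz, 60 pts/decade)."""
    n = int(round(per_decade * math.log10(f_hi / f_lo))) + 1
    return np.logspace(math.log10(f_lo), math.log10(f_hi), n)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LorentzianSum:
    """Finite sum of Lorentzians: terms are (a_k, f_c_k) with a_k the
    zero-frequency density (pA^2/Hz) and f_c_k the corner frequency (Hz)."""

    terms: list
    dominant_index: int | None = None

    def __post_init__(self):
        for a, fc in self.terms:
            if a < 0 or fc <= 0:
                raise ValueError(f"invalid Lorentzian term (a={a}, fc={fc})")

    def __call__(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        S = np.zeros_like(f)
        for a, fc in self.terms:
            S += a / (1.0 + (f / fc) ** 2)
        return S

    def variance(self) -> float:
        """Exact integral over f >= 0: sum a_k f_c_k pi/2."""
        return sum(a * fc * math.pi / 2.0 for a, fc in self.terms)

    def dominant_corner(self) -> float:
        """Corner frequency of the dominant term.

        When built by ``current_psd`` the dominant term is designated in the
        low-open-probability sense (all mostly-closed gates relaxing at full
        multiplicity); otherwise the term contributing the most variance.
        """
        if self.dominant_index is not None:
            return self.terms[self.dominant_index][1]
        return max(self.terms, key=lambda t: t[0] * t[1])[1]

    def dominant_correlation_time(self) -> float:
        """Correlation time (ms) of the dominant term, 1/(2 pi f_c) in seconds -> ms."""
        return 1e3 / (2.0 * math.pi * self.dominant_corner())


@dataclass
class ImpedanceSpectrum:
    """Complex impedance Z(f) in MOhm on a frequency grid (f >= 0, Hz)."""

    freqs: np.ndarray
    Z: np.ndarray

    def magnitude(self) -> np.ndarray:
        return np.abs(self.Z)


@dataclass
class NoiseSummary:
    """Per-population noise summary: current s.d. (pA), voltage s.d. (mV),
    their ratio r = sigma_V/sigma_I (MOhm) and variance contributions."""

    sigma_I: float
    sigma_V: float
    r: float
    variance_contributions: dict


# ---------------------------------------------------------------------------
# Binomial steady-state noise
# ---------------------------------------------------------------------------


def binomial_noise(pop: Population, area: float, V: float):
    """Mean open count, open-count variance and current s.d. at clamped V.

    mean = N p, var = N p (1-p), sigma_I = |gamma (V - E)| sqrt(N p (1-p)).
    """
    N = pop.n_channels(area)
    p = open_probability(pop.scheme, V)
    mean = N * p
    var = N * p * (1.0 - p)
    i_single = pop.scheme.gamma * 1e-3 * (V - pop.scheme.e_rev)  # pA
    sigma_I = abs(i_single) * math.sqrt(var)
    return mean, var, sigma_I


# ---------------------------------------------------------------------------
# Lorentzian current spectra
# ---------------------------------------------------------------------------


def current_psd(pop: Population, area: float, V: float) -> LorentzianSum:
    """Exact multi-Lorentzian current-noise spectrum of a product scheme at clamped V.

    Generated algorithmically from the multinomial expansion of the
    open-state autocovariance; the total integrated power equals the
    binomial variance N i^2 p (1-p) identically.
    """
    scheme = pop.scheme
    if not scheme.subunits:
        raise UnsupportedSchemeError("scheme has no subunits")
    N = pop.n_channels(area)
    i_single = scheme.gamma * 1e-3 * (V - scheme.e_rev)  # pA
    p_open = open_probability(scheme, V)

    xs = [steady_state(s.rates, V) for s in scheme.subunits]
    taus = [time_constant(s.rates, V) for s in scheme.subunits]  # ms
    mults = [s.multiplicity for s in scheme.subunits]

    # dominant-term designation: gates that are mostly closed (x_inf < 1/2)
    # relax at full multiplicity, mostly-open gates contribute their steady
    # part -- the small-open-probability reading of the expansion
    dominant_ks = tuple(m if x < 0.5 else 0 for m, x in zip(mults, xs))

    terms = []
    dominant_index = None
    for ks in itertools.product(*[range(m + 1) for m in mults]):
        if all(k == 0 for k in ks):
            continue  # the constant term cancels against the squared mean
        coeff = p_open
        decay = 0.0  # 1/ms
        for k, m, x, tau in zip(ks, mults, xs, taus):
            coeff *= math.comb(m, k) * x ** (m - k) * (1.0 - x) ** k
            decay += k / tau
        lam_s = decay * 1e3  # 1/s
        fc = lam_s / (2.0 * math.pi)
        a = 4.0 * N * i_single ** 2 * coeff / lam_s  # = 4 sigma_k^2 tau_eff, pA^2/Hz
        if ks == dominant_ks:
            dominant_index = len(terms)
        terms.append((a, fc))
    return LorentzianSum(terms=terms, dominant_index=dominant_index)


# ---------------------------------------------------------------------------
# Impedance
# ---------------------------------------------------------------------------


def quasi_active_admittance(model: MembraneModel, V0: float, freqs) -> np.ndarray:
    """Complex admittance Y(f) in nS of the membrane linearized around V0.

    First-order expansion of each channel current in (dV, dx_j) with
    dx_j(f) = (dx_j_inf/dV) dV / (1 + i 2 pi f tau_j): conductance term
    gbar p_open plus one phenomenological (possibly inductive) term per
    gating variable.
    """
    f = np.asarray(freqs, dtype=float)
    jw = 1j * 2.0 * math.pi * f  # rad/s
    Y = jw * model.capacitance_pF * 1e-3  # pF * rad/s = pS -> nS
    Y = Y + model.g_leak_nS
    for pop in model.populations:
        scheme = pop.scheme
        gbar = scheme.gamma * 1e-3 * pop.density * model.area  # nS
        xs = [steady_state(s.rates, V0) for s in scheme.subunits]
        taus = [time_constant(s.rates, V0) for s in scheme.subunits]  # ms
        p_open = 1.0
        for x, s in zip(xs, scheme.subunits):
            p_open *= x ** s.multiplicity
        Y = Y + gbar * p_open
        drive = V0 - scheme.e_rev
        for j, s in enumerate(scheme.subunits):
            dxdV = steady_state_derivative(s.rates, V0)  # 1/mV
            partial = s.multiplicity * xs[j] ** (s.multiplicity - 1)
            for k, (x, sk) in enumerate(zip(xs, scheme.subunits)):
                if k != j:
                    partial *= x ** sk.multiplicity
            Y = Y + gbar * partial * drive * dxdV / (1.0 + jw * taus[j] * 1e-3)
    return Y


def quasi_active_impedance(model: MembraneModel, V0: float, freqs=None) -> ImpedanceSpectrum:
    """Quasi-active (linearized) impedance Z(f) = 1/Y(f) in MOhm.

    Raises ImpedanceDivergenceError when the admittance (approximately)
    vanishes at some frequency, in which case the sine-injection estimate
    ``empirical_impedance`` should be used instead.
    """
    if freqs is None:
        freqs = default_freq_grid()
    f = np.asarray(freqs, dtype=float)
    Y = quasi_active_admittance(model, V0, f)
    absY = np.abs(Y)
    # detect near-singular admittance relative to the passive DC scale
    scale = model.g_leak_nS + 2.0 * math.pi * model.capacitance_pF * 1e-3 * np.maximum(f, 1.0)
    if np.any(absY < 1e-6 * scale):
        raise ImpedanceDivergenceError(
            "quasi-active admittance vanishes on the grid (divergent impedance); "
            "use empirical_impedance instead")
    Z = 1e3 / Y  # 1/nS = GOhm -> MOhm
    return ImpedanceSpectrum(freqs=f, Z=Z)


def empirical_impedance(model: MembraneModel, V0: float, freqs, amplitude: float = 1.0,
                        dt: float = 0.01, n_periods: int = 6,
                        settle_periods: int = 4) -> ImpedanceSpectrum:
    """Impedance of the deterministic model measured by sine-current injection.

    For each frequency a sinusoidal current of the given amplitude (pA) is
    injected, the transient discarded, and Z obtained from the quadrature
    projection of the voltage response onto the stimulus fundamental.
    Raises AmplitudeTooLargeError when the response leaves the linear regime
    (peak deviation > 2 mV or second-harmonic power > 5% of the fundamental).
    """
    det = with_modes(model, {p.scheme.name: "deterministic" for p in model.populations})
    f = np.asarray(freqs, dtype=float)
    Zs = []
    for fk in f:
        period = 1e3 / fk  # ms
        settle = settle_periods * period + 200.0
        settle_steps = int(round(settle / dt))
        T = settle_steps * dt + n_periods * period
        tr = integrate_deterministic(
            det, I_ext=lambda t: amplitude * np.sin(2e-3 * math.pi * fk * t),
            dt=dt, T=T, V0=V0)
        v = tr.V[settle_steps:]
        t = tr.t[settle_steps:]
        dv = v - np.mean(v)
        if np.max(np.abs(v - V0)) > 2.0:
            raise AmplitudeTooLargeError(
                f"voltage response exceeds +/-2 mV around V0 at f={fk} Hz; reduce amplitude")
        w = 2e-3 * math.pi * fk  # rad/ms
        # complex amplitude of the fundamental and second harmonic
        c1 = 2.0 * np.mean(dv * np.exp(-1j * w * t))
        c2 = 2.0 * np.mean(dv * np.exp(-2j * w * t))
        if np.abs(c2) ** 2 > 0.05 * np.abs(c1) ** 2:
            raise AmplitudeTooLargeError(
                f"second-harmonic distortion exceeds 5% at f={fk} Hz; reduce amplitude")
        # stimulus complex amplitude is amplitude * (-i) relative to exp(i w t)
        Zs.append(c1 / (amplitude * -1j) * 1e3)  # mV/pA = GOhm -> MOhm
    return ImpedanceSpectrum(freqs=f, Z=np.asarray(Zs))


# ---------------------------------------------------------------------------
# Voltage noise
# ---------------------------------------------------------------------------


def voltage_psd(S_I, Z: ImpedanceSpectrum):
    """Voltage-noise spectrum S_V(f) = S_I(f) |Z(f)|^2 (mV^2/Hz).

    ``S_I`` may be a LorentzianSum (evaluated on Z's grid), a dict of
    population name -> LorentzianSum (per-population and summed spectra are
    returned), or a sampled array on the same grid.
    """
    f = Z.freqs
    zsq = (np.abs(Z.Z) * PA_MOHM_TO_MV) ** 2  # (mV/pA)^2
    if isinstance(S_I, dict):
        per = {name: spec(f) * zsq for name, spec in S_I.items()}
        total = np.sum(list(per.values()), axis=0)
        return f, total, per
    if isinstance(S_I, LorentzianSum):
        return f, S_I(f) * zsq
    S_I = np.asarray(S_I, dtype=float)
    if S_I.shape != f.shape:
        raise GridError(f"S_I grid length {S_I.shape} does not match Z grid {f.shape}")
    return f, S_I * zsq


def voltage_variance(freqs, S_V) -> float:
    """Integrate a sampled voltage-noise spectrum over f >= 0 (mV^2).

    Trapezoidal rule on the grid plus an analytic 1/f^2 tail beyond the last
    point (integral S_end * f_end). Raises GridError when the spectrum has
    not started to decay (last-decade contribution > 1% of the total and
    still flat), which signals a too-short grid.
    """
    f = np.asarray(freqs, dtype=float)
    S = np.asarray(S_V, dtype=float)
    if f.shape != S.shape:
        raise GridError("frequency and spectrum grids differ in length")
    body = np.trapezoid(S, f)
    tail = S[-1] * f[-1]  # integral of S[-1] (f[-1]/f)^2 from f[-1] to inf
    total = body + tail
    # decay check: the last decade must contribute little and be falling
    last_decade = f >= f[-1] / 10.0
    contrib = np.trapezoid(S[last_decade], f[last_decade]) + tail
    if contrib > 0.01 * total and S[-1] > 0.5 * S[last_decade][0]:
        raise GridError("spectrum does not decay on the grid; extend the frequency range")
    return float(total)


def filter_ratio(pop: Population, model: MembraneModel, V0: float,
                 Z: ImpedanceSpectrum | None = None) -> NoiseSummary:
    """Membrane-filtering ratio r = sigma_V / sigma_I (MOhm) for one population.

    sigma_I comes from the exact binomial variance; sigma_V from integrating
    the population's Lorentzian spectrum through |Z|^2 on the standard grid.
    """
    if Z is None:
        Z = quasi_active_impedance(model, V0)
    S_I = current_psd(pop, model.area, V0)
    f, S_V = voltage_psd(S_I, Z)
    var_V = voltage_variance(f, S_V)
    _, _, sigma_I = binomial_noise(pop, model.area, V0)
    sigma_V = math.sqrt(var_V)
    r = sigma_V / sigma_I / PA_MOHM_TO_MV if sigma_I > 0 else float("nan")
    return NoiseSummary(sigma_I=sigma_I, sigma_V=sigma_V, r=r,
                        variance_contributions={pop.scheme.name: var_V})


def noise_report(model: MembraneModel, V0: float | None = None,
                 Z: ImpedanceSpectrum | None = None):
    """Per-population noise decomposition at the operating point.

    Returns a pandas DataFrame with, per population: open probability, N,
    driving force, sigma_I, dominant corner frequency, sigma_V, r and the
    share of the summed voltage variance.
    """
    import pandas as pd
    from .simulator import resting_state

    if V0 is None:
        V0 = resting_state(model).v_rest
    if Z is None:
        Z = quasi_active_impedance(model, V0)
    rows = []
    for pop in model.populations:
        p = open_probability(pop.scheme, V0)
        N = pop.n_channels(model.area)
        drive = V0 - pop.scheme.e_rev
        spec = current_psd(pop, model.area, V0)
        summ = filter_ratio(pop, model, V0, Z=Z)
        rows.append({
            "population": pop.scheme.name,
            "p_open": p,
            "N": N,
            "driving_force_mV": drive,
            "sigma_I_pA": summ.sigma_I,
            "dominant_fc_Hz": spec.dominant_corner(),
            "sigma_V_mV": summ.sigma_V,
            "r_MOhm": summ.r,
            "voltage_variance_mV2": summ.sigma_V ** 2,
        })
    df = pd.DataFrame(rows)
    total = df["voltage_variance_mV2"].sum()
    df["variance_share"] = df["voltage_variance_mV2"] / total if total > 0 else 0.0
    return df
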