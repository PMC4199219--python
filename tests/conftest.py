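"""Shared fixtures: standard models and the session-scoped simulated traces
that several test modules analyze (generated once, deterministically)."""

import numpy as np
import pytest

import channelnoise.analysis as A
import channelnoise.simulator as S


@pytest.fixture(scope="session")
def hh1000():
    return S.hh_membrane(1000.0)


@pytest.fixture(scope="session")
def hh_rest(hh1000):
    return S.resting_state(hh1000).v_rest


@pytest.fixture(scope="session")
def clamp_trace(hh1000):
    """Voltage-clamp run at -65 mV, 1000 um^2: open-count statistics and
    current periodograms are checked against the binomial/Lorentzian theory."""
    return S.voltage_clamp(hh1000, -65.0, dt=0.01, T=3000.0, seed=101)


@pytest.fixture(scope="session")
def spiking_trace_100():
    """Spontaneously spiking fully stochastic patch (100 um^2, 12 s)."""
    return S.simulate_stochastic(S.hh_membrane(100.0), dt=0.01, T=12000.0, seed=42)


@pytest.fixture(scope="session")
def spiking_spikes_100(spiking_trace_100):
    return A.detect_spikes(spiking_trace_100)


@pytest.fixture(scope="session")
def spiking_trace_na_only_50():
    """Na+-only stochastic patch (K+ deterministic), 50 um^2, 12 s: the
    contrast case where spikes must be Na+-fluctuation driven."""
    model = S.with_modes(S.hh_membrane(50.0), {"hh_k": "deterministic"})
    return S.simulate_stochastic(model, dt=0.01, T=12000.0, seed=43)


def _rate(area, modes, T, seed):
    est = S.spontaneous_rate(S.hh_membrane(area), modes=modes, T_total=T,
                             seed=seed, dt=0.01)
    return est


@pytest.fixture(scope="session")
def rates_all_stochastic():
    """Spontaneous rate of the fully stochastic patch across areas (Hz)."""
    durations = {50.0: 4000.0, 75.0: 4000.0, 100.0: 4000.0,
                 150.0: 10000.0, 200.0: 10000.0, 400.0: 6000.0}
    return {a: _rate(a, None, T, seed=20240 + int(a)) for a, T in durations.items()}


@pytest.fixture(scope="session")
def rates_k_only():
    """K+-only stochastic (Na+ deterministic) rates at matched areas."""
    return {a: _rate(a, {"hh_na": "deterministic"}, 6000.0, seed=30240 + int(a))
            for a in (50.0, 100.0)}


@pytest.fixture(scope="session")
def rates_na_only():
    """Na+-only stochastic (K+ deterministic) rates at matched areas."""
    return {a: _rate(a, {"hh_k": "deterministic"}, 6000.0, seed=40240 + int(a))
            for a in (50.0, 100.0)}
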