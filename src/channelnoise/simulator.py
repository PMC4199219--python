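"""Single-compartment membrane simulation with stochastic or deterministic channel gating.

The membrane obeys ``C dV/dt = -sum_x g_x (V - E_x) - g_leak (V - E_leak) + I_inj``
with each channel population either in

* deterministic mode: continuum gating variables relaxing as
  ``dx/dt = (x_inf(V) - x)/tau_x(V)``, conductance ``gbar * prod x**mult``;
* stochastic mode: ``N = round(density * area)`` discrete channels, each an
  aggregated Markov chain over subunit on-counts, advanced per time step with
  exact two-state subunit transition probabilities (binomial transition
  counts within the channel, multinomial redistribution across the
  population's state-count vector).

Voltage is advanced by exponential Euler with conductances frozen per step,
which is stable through the stiff spike upstroke. Internal units: mV, ms,
pA, nS, pF (1 uF/cm^2 over 1 um^2 = 0.01 pF).

Gating lookup tables are cached on a 0.05 mV voltage quantization grid:
transition probabilities change by well under 1% across one bin, far below
the sampling noise of any stochastic run, and the caching makes the
per-step cost independent of the kinetics' complexity.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .kinetics import (
    ChannelScheme,
    get_scheme,
    open_probability,
    steady_state,
)

__all__ = [
    "Population",
    "MembraneModel",
    "Trace",
    "SpikeTrain",
    "RateEstimate",
    "RestingState",
    "NoRestError",
    "InstabilityError",
    "hh_membrane",
    "ca1_membrane",
    "with_modes",
    "with_area",
    "resting_state",
    "integrate_deterministic",
    "simulate_stochastic",
    "voltage_clamp",
    "spontaneous_rate",
    "fI_curve",
    "DEFAULT_DT",
    "DEFAULT_THRESHOLD",
    "DEFAULT_REFRACTORY",
]

DEFAULT_DT = 0.005  # ms
DEFAULT_THRESHOLD = -20.0  # mV, upward-crossing spike detection
DEFAULT_REFRACTORY = 2.0  # ms
_VBIN = 0.05  # mV quantization of gating lookup tables
_BURN_IN = 200.0  # ms discarded before spontaneous-rate estimation


class NoRestError(RuntimeError):
    """No resting-potential root found in the search window."""


class InstabilityError(RuntimeError):
    """Numerical blow-up (|V| > 200 mV); reduce dt."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """One channel population: kinetic scheme, areal density (1/um^2) and gating mode."""

    scheme: ChannelScheme
    density: float
    mode: str = "stochastic"

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.mode not in ("stochastic", "deterministic"):
            raise ValueError(f"mode must be 'stochastic' or 'deterministic', got {self.mode!r}")

    def n_channels(self, area: float) -> int:
        return int(round(self.density * area))


@dataclass(frozen=True)
class MembraneModel:
    """Isopotential patch: capacitance density (uF/cm^2), area (um^2), channel
    populations and deterministic Ohmic leaks given as (pS/um^2, E_rev mV)."""

    c_m: float
    area: float
    populations: tuple
    leaks: tuple

    def __post_init__(self):
        if self.c_m <= 0 or self.area <= 0:
            raise ValueError("c_m and area must be > 0")
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "leaks", tuple(tuple(l) for l in self.leaks))

    @property
    def capacitance_pF(self) -> float:
        return self.c_m * self.area * 1e-2

    @property
    def g_leak_nS(self) -> float:
        return sum(d for d, _ in self.leaks) * self.area * 1e-3

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.scheme.name == name:
                return p
        raise KeyError(f"no population named {name!r}")


@dataclass
class Trace:
    """Simulated time series. ``currents`` holds per-population total ionic
    current gamma*(V - E)*open (pA, outward positive); ``gating`` holds open
    channel counts (stochastic) or open fractions (deterministic)."""

    dt: float
    t0: float
    V: np.ndarray
    currents: dict
    injected: np.ndarray
    gating: dict

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.V))


@dataclass
class SpikeTrain:
    """Detected spike times (ms), with the detection rule that produced them."""

    times: np.ndarray
    threshold: float
    refractory: float

    def __len__(self):
        return len(self.times)

    def rate_hz(self, duration_ms: float) -> float:
        return 1e3 * len(self.times) / duration_ms


@dataclass
class RateEstimate:
    """Spontaneous firing-rate estimate with a Poisson-count standard error."""

    rate: float  # Hz
    se: float  # Hz
    n_spikes: int
    duration: float  # ms
    upper95: float  # one-sided 95% bound, meaningful when n_spikes == 0


@dataclass
class RestingState:
    v_rest: float
    gating: dict  # population name -> array of subunit steady states


# ---------------------------------------------------------------------------
# Standard model factories
# ---------------------------------------------------------------------------


def hh_membrane(area: float = 1000.0, na_mode: str = "stochastic",
                k_mode: str = "stochastic") -> MembraneModel:
    """Standard squid-axon patch: C_m 1 uF/cm^2, 60 Na+ and 18 K+ channels per
    um^2 (20 pS each, E_Na +50 / E_K -77 mV), 3 pS/um^2 leak reversing at -55 mV."""
    return MembraneModel(
        c_m=1.0,
        area=area,
        populations=(
            Population(get_scheme("hh_na"), density=60.0, mode=na_mode),
            Population(get_scheme("hh_k"), density=18.0, mode=k_mode),
        ),
        leaks=((3.0, -55.0),),
    )


def ca1_membrane(area: float = 1000.0, mode: str = "stochastic") -> MembraneModel:
    """Single-compartment CA1 pyramidal-cell patch (approximate kinetics):
    20 Na+, 20 Kdr and 24 Ka channels per um^2 at 20 pS, plus Na+- and
    K+-permeable leaks (0.065 / 0.185 pS/um^2, i.e. 0.025 mS/cm^2 total)."""
    return MembraneModel(
        c_m=1.0,
        area=area,
        populations=(
            Population(get_scheme("ca1_na"), density=20.0, mode=mode),
            Population(get_scheme("ca1_kdr"), density=20.0, mode=mode),
            Population(get_scheme("ca1_ka"), density=24.0, mode=mode),
        ),
        leaks=((0.065, 55.0), (0.185, -90.0)),
    )


def with_modes(model: MembraneModel, modes: dict) -> MembraneModel:
    """Copy of the model with per-population gating modes replaced."""
    pops = []
    for p in model.populations:
        if p.scheme.name in modes:
            p = replace(p, mode=modes[p.scheme.name])
        pops.append(p)
    unknown = set(modes) - {p.scheme.name for p in model.populations}
    if unknown:
        raise KeyError(f"modes given for unknown populations: {sorted(unknown)}")
    return replace(model, populations=tuple(pops))


def with_area(model: MembraneModel, area: float) -> MembraneModel:
    return replace(model, area=area)


# ---------------------------------------------------------------------------
# Resting state
# ---------------------------------------------------------------------------


def _net_current(model: MembraneModel, V: float) -> float:
    """Net depolarizing membrane current (pA) with all gating at steady state."""
    I = 0.0
    for p in model.populations:
        gbar = p.scheme.gamma * 1e-3 * p.density * model.area  # nS
        I += gbar * open_probability(p.scheme, V) * (p.scheme.e_rev - V)
    for dens, erev in model.leaks:
        I += dens * 1e-3 * model.area * (erev - V)
    return I


def resting_state(model: MembraneModel, v_lo: float = -90.0, v_hi: float = -40.0,
                  v_target: float = -65.0) -> RestingState:
    """Resting potential: root of the steady-state current balance nearest v_target.

    Scans [v_lo, v_hi] for sign changes and polishes each with Brent's method.
    Raises NoRestError if no root exists in the window.
    """
    from scipy.optimize import brentq

    grid = np.arange(v_lo, v_hi + 0.25, 0.25)
    f = np.array([_net_current(model, v) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0:
            roots.append(float(grid[i]))
        elif f[i] * f[i + 1] < 0:
            roots.append(float(brentq(lambda v: _net_current(model, v), grid[i], grid[i + 1],
                                      xtol=1e-10)))
    if f[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        raise NoRestError(f"no resting potential in [{v_lo}, {v_hi}] mV")
    v_rest = min(roots, key=lambda r: abs(r - v_target))
    gating = {
        p.scheme.name: np.array([steady_state(s.rates, v_rest) for s in p.scheme.subunits])
        for p in model.populations
    }
    return RestingState(v_rest=v_rest, gating=gating)


# ---------------------------------------------------------------------------
# Gating engines
# ---------------------------------------------------------------------------

_COMB = {m: np.array([[math.comb(k, i) if i <= k else 0 for i in range(m + 1)]
                      for k in range(m + 1)], dtype=float) for m in range(1, 5)}
# scatter matrix S[(i,u), j] = 1 if i+u == j, for summing the stay/flip convolution
_SCATTER = {}
for _m in range(1, 5):
    _S = np.zeros(((_m + 1) * (_m + 1), _m + 1))
    for _i in range(_m + 1):
        for _u in range(_m + 1):
            if _i + _u <= _m:
                _S[_i * (_m + 1) + _u, _i + _u] = 1.0
    _SCATTER[_m] = _S


def _subunit_step_probs(alpha: float, beta: float, dt: float):
    """Exact two-state transition probabilities over one step of length dt."""
    tot = alpha + beta
    if tot <= 0.0:
        return 0.0, 0.0
    relax = -math.expm1(-tot * dt)
    return (alpha / tot) * relax, (beta / tot) * relax  # P(off->on), P(on->off)


def _type_transition_matrix(m: int, p01: float, p10: float) -> np.ndarray:
    """(m+1)x(m+1) matrix over on-counts of m independent two-state subunits."""
    i = np.arange(m + 1, dtype=float)
    comb = _COMB[m]
    q_on = 1.0 - p10
    # stay[k, i]: of k on-subunits, i remain on
    stay = np.where(i[None, :] <= i[:, None],
                    comb * q_on ** i[None, :] * p10 ** np.maximum(i[:, None] - i[None, :], 0.0),
                    0.0)
    # flip[k, u]: of m-k off-subunits, u turn on
    off = (m - i)[:, None]
    u = i[None, :]
    comb_off = np.array([[math.comb(m - k, uu) if uu <= m - k else 0 for uu in range(m + 1)]
                         for k in range(m + 1)], dtype=float)
    flip = np.where(u <= off, comb_off * p01 ** u * (1.0 - p01) ** (off - u), 0.0)
    T = (stay[:, :, None] * flip[:, None, :]).reshape(m + 1, -1) @ _SCATTER[m]
    T /= T.sum(axis=1, keepdims=True)
    return T


class _StochasticPop:
    """State-count vector over the aggregated per-channel Markov states."""

    def __init__(self, pop: Population, area: float, dt: float, rng: np.random.Generator):
        self.name = pop.scheme.name
        self.scheme = pop.scheme
        self.N = pop.n_channels(area)
        if self.N < 1:
            raise ValueError(f"stochastic population {self.name!r} has N < 1; "
                             "increase area or density, or use deterministic mode")
        self.gamma_nS = pop.scheme.gamma * 1e-3
        self.e_rev = pop.scheme.e_rev
        self.mults = [s.multiplicity for s in pop.scheme.subunits]
        self.rates = [s.rates for s in pop.scheme.subunits]
        self.dt = dt
        self.rng = rng
        self.open_index = len(self._state_space()) - 1
        self._cache: dict = {}

    def _state_space(self):
        import itertools
        return list(itertools.product(*[range(m + 1) for m in self.mults]))

    def _channel_matrix(self, vbin: int) -> np.ndarray:
        T = self._cache.get(vbin)
        if T is None:
            V = vbin * _VBIN
            T = np.ones((1, 1))
            for mult, rp in zip(self.mults, self.rates):
                p01, p10 = _subunit_step_probs(float(rp.alpha(V)), float(rp.beta(V)), self.dt)
                T = np.kron(T, _type_transition_matrix(mult, p01, p10))
            self._cache[vbin] = T
        return T

    def init_stationary(self, V: float):
        """Draw the state-count vector from the product-binomial stationary law at V."""
        pi = np.ones(1)
        for mult, rp in zip(self.mults, self.rates):
            x = steady_state(rp, V)
            k = np.arange(mult + 1)
            pmf = np.array([math.comb(mult, int(kk)) for kk in k]) * x ** k * (1 - x) ** (mult - k)
            pi = np.kron(pi, pmf)
        pi = pi / pi.sum()
        self.counts = self.rng.multinomial(self.N, pi)

    def step(self, V: float):
        vbin = int(round(V / _VBIN))
        T = self._channel_matrix(vbin)
        moved = self.rng.multinomial(self.counts, T)
        self.counts = moved.sum(axis=0)

    @property
    def n_open(self) -> int:
        return int(self.counts[self.open_index])

    def conductance_nS(self) -> float:
        return self.gamma_nS * self.counts[self.open_index]


class _DeterministicPop:
    """Continuum gating variables with exact exponential relaxation per step.

    Pure scalar arithmetic: the per-step cost of long deterministic runs is
    dominated by Python overhead, so gating state is a plain list of floats
    and the voltage-binned tables hold float tuples. Tables are linearly
    interpolated between adjacent bins so small-signal responses stay smooth
    in V.
    """

    def __init__(self, pop: Population, area: float, dt: float):
        self.name = pop.scheme.name
        self.scheme = pop.scheme
        self.gbar_nS = pop.scheme.gamma * 1e-3 * pop.density * area
        self.e_rev = pop.scheme.e_rev
        self.mults = [s.multiplicity for s in pop.scheme.subunits]
        self.rates = [s.rates for s in pop.scheme.subunits]
        self.n_sub = len(self.rates)
        self.dt = dt
        self._cache: dict = {}

    def init_steady(self, V: float):
        self.x = [steady_state(rp, V) for rp in self.rates]

    def _tables(self, vbin: int):
        tab = self._cache.get(vbin)
        if tab is None:
            V = vbin * _VBIN
            xinf, decay = [], []
            for rp in self.rates:
                a, b = float(rp.alpha(V)), float(rp.beta(V))
                tot = a + b
                xinf.append(a / tot if tot > 0 else 0.0)
                decay.append(-math.expm1(-tot * self.dt))
            tab = (tuple(xinf), tuple(decay))
            self._cache[vbin] = tab
        return tab

    def step(self, V: float):
        b = math.floor(V / _VBIN)
        w = V / _VBIN - b
        x0, r0 = self._tables(b)
        x1, r1 = self._tables(b + 1)
        x = self.x
        for j in range(self.n_sub):
            xinf = x0[j] + (x1[j] - x0[j]) * w
            relax = r0[j] + (r1[j] - r0[j]) * w
            x[j] += (xinf - x[j]) * relax

    def open_fraction(self) -> float:
        p = 1.0
        for xj, mj in zip(self.x, self.mults):
            p *= xj ** mj
        return p

    def conductance_nS(self) -> float:
        return self.gbar_nS * self.open_fraction()


# ---------------------------------------------------------------------------
# Core integration loop
# ---------------------------------------------------------------------------


def _pop_rng(seed: int, name: str) -> np.random.Generator:
    """Named-stream generator: each population's stream depends only on the
    master seed and its own scheme name, so switching one population's mode
    leaves the others' random streams untouched."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _as_current_array(I_ext, n_steps: int, dt: float, t0: float = 0.0) -> np.ndarray:
    if I_ext is None:
        return np.zeros(n_steps)
    if callable(I_ext):
        return np.asarray(I_ext(t0 + dt * np.arange(n_steps)), dtype=float) * np.ones(n_steps)
    arr = np.asarray(I_ext, dtype=float)
    if arr.ndim == 0:
        return np.full(n_steps, float(arr))
    if len(arr) < n_steps:
        raise ValueError(f"injected current series too short: {len(arr)} < {n_steps}")
    return arr[:n_steps]


def _run(model: MembraneModel, I_ext, dt: float, T: float, seed=None, V0=None,
         clamp=None, record: bool = True, threshold: float = DEFAULT_THRESHOLD,
         refractory: float = DEFAULT_REFRACTORY, init_gating: str = "steady"):
    """Shared integration engine.

    Returns (Trace | None, spike_times list). With record=False only the
    on-the-fly detected spike times are kept, which bounds memory for long
    rate-estimation runs.
    """
    n_steps = int(round(T / dt))
    if V0 is None:
        V0 = resting_state(model).v_rest if clamp is None else clamp
    inj = _as_current_array(I_ext, n_steps, dt)

    stoch, det = [], []
    for p in model.populations:
        if p.mode == "stochastic":
            sp = _StochasticPop(p, model.area, dt, _pop_rng(0 if seed is None else seed, p.scheme.name))
            if init_gating == "steady":
                sp.init_stationary(V0)
            stoch.append(sp)
        else:
            dp = _DeterministicPop(p, model.area, dt)
            dp.init_steady(V0)
            det.append(dp)
    if stoch and seed is None:
        raise ValueError("stochastic simulation requires an explicit seed")

    C = model.capacitance_pF
    g_leak = 0.0
    gE_leak = 0.0
    for dens, erev in model.leaks:
        g = dens * 1e-3 * model.area
        g_leak += g
        gE_leak += g * erev

    if record:
        V_out = np.empty(n_steps + 1)
        cur_out = {p.name: np.empty(n_steps + 1) for p in stoch + det}
        gat_out = {p.name: np.empty(n_steps + 1) for p in stoch + det}
        inj_out = np.concatenate([inj, [inj[-1] if n_steps else 0.0]])
    spikes = []
    last_spike = -math.inf

    V = float(V0)
    for i in range(n_steps + 1):
        if record:
            V_out[i] = V
            for p in stoch:
                cur_out[p.name][i] = p.gamma_nS * p.n_open * (V - p.e_rev)
                gat_out[p.name][i] = p.n_open
            for p in det:
                cur_out[p.name][i] = p.gbar_nS * p.open_fraction() * (V - p.e_rev)
                gat_out[p.name][i] = p.open_fraction()
        if i == n_steps:
            break

        # advance gating at the current voltage
        for p in stoch:
            p.step(V)
        for p in det:
            p.step(V)

        if clamp is not None:
            continue

        # exponential-Euler voltage update with post-step conductances
        g_tot = g_leak
        gE = gE_leak
        for p in stoch:
            g = p.conductance_nS()
            g_tot += g
            gE += g * p.e_rev
        for p in det:
            g = p.conductance_nS()
            g_tot += g
            gE += g * p.e_rev
        V_inf = (gE + inj[i]) / g_tot
        V_new = V_inf + (V - V_inf) * math.exp(-dt * g_tot / C)
        t_new = (i + 1) * dt
        if V < threshold <= V_new and t_new - last_spike >= refractory:
            spikes.append(t_new)
            last_spike = t_new
        V = V_new
        if abs(V) > 200.0:
            raise InstabilityError(f"voltage blew up (|V| > 200 mV) at t={t_new:.3f} ms "
                                   f"with dt={dt}; reduce dt")

    trace = None
    if record:
        if clamp is not None:
            V_out[:] = clamp
        trace = Trace(dt=dt, t0=0.0, V=V_out, currents=cur_out, injected=inj_out, gating=gat_out)
    return trace, spikes


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def integrate_deterministic(model: MembraneModel, I_ext=None, dt: float = DEFAULT_DT,
                            T: float = 100.0, V0=None) -> Trace:
    """Integrate the coupled voltage/gating ODEs with all populations deterministic."""
    det_model = with_modes(model, {p.scheme.name: "deterministic" for p in model.populations})
    trace, _ = _run(det_model, I_ext, dt, T, V0=V0, record=True)
    return trace


def simulate_stochastic(model: MembraneModel, I_ext=None, dt: float = DEFAULT_DT,
                        T: float = 100.0, seed: int = 0, V0=None) -> Trace:
    """Simulate with each population in its configured mode (stochastic populations
    advance as discrete Markov channel counts). Reproducible given (seed, dt)."""
    trace, _ = _run(model, I_ext, dt, T, seed=seed, V0=V0, record=True)
    return trace


def voltage_clamp(model: MembraneModel, V_hold: float, dt: float = DEFAULT_DT,
                  T: float = 100.0, seed: int = 0) -> Trace:
    """Stochastic gating at fixed voltage; currents are gamma*(V_hold - E)*count."""
    trace, _ = _run(model, None, dt, T, seed=seed, clamp=V_hold, record=True)
    return trace


def spontaneous_rate(model: MembraneModel, modes: dict | None = None, T_total: float = 10_000.0,
                     seed: int = 0, threshold: float = DEFAULT_THRESHOLD,
                     dt: float = DEFAULT_DT, refractory: float = DEFAULT_REFRACTORY,
                     burn_in: float = _BURN_IN) -> RateEstimate:
    """Spontaneous firing rate with zero injected current.

    The first ``burn_in`` ms are discarded. The standard error is
    sqrt(n)/duration (Poisson counting); with zero spikes, ``upper95`` is the
    one-sided 95% bound 3/duration.
    """
    m = with_modes(model, modes) if modes else model
    if all(p.mode == "deterministic" for p in m.populations):
        seed = None  # fully deterministic: no randomness involved
    _, spikes = _run(m, None, dt, T_total, seed=seed, record=False,
                     threshold=threshold, refractory=refractory)
    kept = [t for t in spikes if t >= burn_in]
    dur = T_total - burn_in
    n = len(kept)
    return RateEstimate(rate=1e3 * n / dur, se=1e3 * math.sqrt(n) / dur, n_spikes=n,
                        duration=dur, upper95=1e3 * (n + 3.0) / dur)


def fI_curve(model: MembraneModel, currents: Sequence[float], dt: float = DEFAULT_DT,
             T: float = 1000.0, discard: float = 200.0,
             threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Deterministic steady-state firing rate (Hz) for each DC current (pA)."""
    det_model = with_modes(model, {p.scheme.name: "deterministic" for p in model.populations})
    rest = resting_state(det_model).v_rest
    rates = []
    for I in currents:
        _, spikes = _run(det_model, float(I), dt, T, V0=rest, record=False,
                         threshold=threshold)
        n = sum(1 for t in spikes if t >= discard)
        rates.append(1e3 * n / (T - discard))
    return np.asarray(rates)


def _count_spikes_with_current(model: MembraneModel, I_series: np.ndarray, dt: float,
                               T: float, V0=None, threshold: float = DEFAULT_THRESHOLD,
                               discard: float = _BURN_IN) -> int:
    """Lean helper for noise-injection rate estimation (no trace storage)."""
    _, spikes = _run(model, I_series, dt, T, V0=V0, record=False, threshold=threshold)
    return sum(1 for t in spikes if t >= discard)
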