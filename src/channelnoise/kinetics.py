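"""Kinetic schemes of voltage-gated ion channels built from independent two-state subunits.

A channel is described by a set of subunit types (e.g. the Hodgkin-Huxley
``m``, ``h``, ``n`` gates), each an independent two-state Markov switch with
voltage-dependent opening rate ``alpha(V)`` and closing rate ``beta(V)``.
A channel with subunit multiplicities ``(k_1, ..., k_J)`` conducts iff every
subunit copy is in its on-state, so the steady-state open probability is
``prod_j x_j_inf(V)**k_j``.

Units: voltage mV, time ms, rates 1/ms, single-channel conductance pS.
Kinetics are those of the squid giant axon at 6.3 degC; no temperature
scaling is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RatePair",
    "SubunitSpec",
    "ChannelScheme",
    "MarkovExpansion",
    "DegenerateRatesError",
    "UnsupportedSchemeError",
    "UnknownSchemeError",
    "make_rate",
    "hh_rates",
    "steady_state",
    "time_constant",
    "open_probability",
    "expand_markov",
    "stationary_distribution",
    "get_scheme",
    "register_scheme",
    "BUILTIN_SCHEMES",
]


class DegenerateRatesError(ValueError):
    """Raised when alpha(V) + beta(V) == 0 and a steady state or time constant is requested."""


class UnsupportedSchemeError(ValueError):
    """Raised when an operation requires an independent-subunit product scheme."""


class UnknownSchemeError(KeyError):
    """Raised when a channel scheme name is not registered."""


# ---------------------------------------------------------------------------
# Rate functional forms
#
# Three forms cover all built-in channels:
#   linexp:   a*(V+c) / (1 - exp(-(V+c)/d))     (removable singularity at V=-c)
#   exp:      a * exp(-(V+c)/d)
#   logistic: a / (1 + exp(-(V+c)/d))
# ---------------------------------------------------------------------------

_SINGULARITY_EPS = 1e-7  # |(V+c)/d| below this uses the series limit a*d


def _linexp(a: float, c: float, d: float) -> Callable:
    def rate(V):
        V = np.asarray(V, dtype=float)
        u = (V + c) / d
        # a*(V+c)/(1-exp(-u)) -> a*d as u -> 0 (removable singularity)
        with np.errstate(over="ignore"):
            denom = -np.expm1(-u)
        safe = np.abs(u) > _SINGULARITY_EPS
        out = np.where(safe, a * (V + c) / np.where(safe, denom, 1.0), a * d)
        return out if out.ndim else float(out)

    return rate


def _exp(a: float, c: float, d: float) -> Callable:
    def rate(V):
        V = np.asarray(V, dtype=float)
        out = a * np.exp(-(V + c) / d)
        return out if out.ndim else float(out)

    return rate


def _logistic(a: float, c: float, d: float) -> Callable:
    def rate(V):
        V = np.asarray(V, dtype=float)
        out = a / (1.0 + np.exp(-(V + c) / d))
        return out if out.ndim else float(out)

    return rate


RATE_FORMS = {"linexp": _linexp, "exp": _exp, "logistic": _logistic}


def make_rate(form: str, a: float, c: float, d: float) -> Callable:
    """Build a rate function ``V -> 1/ms`` from one of the supported functional forms."""
    try:
        factory = RATE_FORMS[form]
    except KeyError:
        raise ValueError(f"unknown rate form {form!r}; supported: {sorted(RATE_FORMS)}") from None
    return factory(a, c, d)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatePair:
    """Opening/closing rate functions of one two-state subunit.

    Both map voltage (mV) to a non-negative, finite rate (1/ms) on the
    physiological range [-120, +60] mV.
    """

    alpha: Callable
    beta: Callable


@dataclass(frozen=True)
class SubunitSpec:
    """A named subunit type with its multiplicity within the channel."""

    name: str
    multiplicity: int
    rates: RatePair

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")


@dataclass(frozen=True)
class ChannelScheme:
    """Full kinetic description of one channel type.

    gamma is the single-channel conductance in pS, e_rev the reversal
    potential in mV. The channel is open iff every subunit copy is on.
    """

    name: str
    subunits: tuple
    gamma: float
    e_rev: float

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        object.__setattr__(self, "subunits", tuple(self.subunits))

    @property
    def n_states(self) -> int:
        return int(np.prod([s.multiplicity + 1 for s in self.subunits]))


@dataclass
class MarkovExpansion:
    """Aggregated Markov chain over per-channel subunit on-counts.

    ``states[i]`` is a tuple of on-counts per subunit type; ``rate_matrix``
    is the generator Q (1/ms) with rows summing to zero;
    ``open_state_index`` is the unique state where every count equals its
    multiplicity.
    """

    states: list
    rate_matrix: np.ndarray
    open_state_index: int


# ---------------------------------------------------------------------------
# Hodgkin-Huxley squid-axon rates (6.3 degC)
# ---------------------------------------------------------------------------

_HH_RATES = {
    "m": RatePair(alpha=_linexp(0.1, 40.0, 10.0), beta=_exp(4.0, 65.0, 18.0)),
    "h": RatePair(alpha=_exp(0.07, 65.0, 20.0), beta=_logistic(1.0, 35.0, 10.0)),
    "n": RatePair(alpha=_linexp(0.01, 55.0, 10.0), beta=_exp(0.125, 65.0, 80.0)),
}


def hh_rates(subunit_name: str, V):
    """Evaluate the classic squid-axon opening/closing rates of gate m, h or n.

    Returns ``(alpha, beta)`` in 1/ms. The removable singularities of the
    alpha_m / alpha_n forms (at -40 and -55 mV) evaluate to their analytic
    limits.
    """
    try:
        pair = _HH_RATES[subunit_name]
    except KeyError:
        raise ValueError(f"unknown HH subunit {subunit_name!r}; expected one of m, h, n") from None
    return pair.alpha(V), pair.beta(V)


# ---------------------------------------------------------------------------
# Steady-state quantities
# ---------------------------------------------------------------------------


def steady_state(rates: RatePair, V):
    """Steady-state on-probability alpha/(alpha+beta) of a two-state subunit."""
    a, b = rates.alpha(V), rates.beta(V)
    tot = np.asarray(a) + np.asarray(b)
    if np.any(tot == 0):
        raise DegenerateRatesError(f"alpha + beta == 0 at V={V}")
    out = np.asarray(a) / tot
    return float(out) if out.ndim == 0 else out


def time_constant(rates: RatePair, V):
    """Relaxation time constant 1/(alpha+beta) in ms."""
    a, b = rates.alpha(V), rates.beta(V)
    tot = np.asarray(a) + np.asarray(b)
    if np.any(tot == 0):
        raise DegenerateRatesError(f"alpha + beta == 0 at V={V}")
    out = 1.0 / tot
    return float(out) if out.ndim == 0 else out


def open_probability(scheme: ChannelScheme, V):
    """Steady-state open probability prod_j x_j_inf(V)**multiplicity_j."""
    p = 1.0
    for sub in scheme.subunits:
        p = p * steady_state(sub.rates, V) ** sub.multiplicity
    return p


def steady_state_derivative(rates: RatePair, V: float, h: float = 1e-3) -> float:
    """d x_inf / dV by central difference (1/mV); h in mV."""
    return (steady_state(rates, V + h) - steady_state(rates, V - h)) / (2.0 * h)


# ---------------------------------------------------------------------------
# Aggregated Markov expansion
# ---------------------------------------------------------------------------


def expand_markov(scheme: ChannelScheme, V: float) -> MarkovExpansion:
    """Expand a product scheme into its aggregated-state Markov generator at voltage V.

    States are tuples of on-counts per subunit type. With k of m copies on,
    off->on transitions occur at rate (m-k)*alpha and on->off at k*beta
    (independent subunits, binomial counting).
    """
    mults = [s.multiplicity for s in scheme.subunits]
    alphas = [float(s.rates.alpha(V)) for s in scheme.subunits]
    betas = [float(s.rates.beta(V)) for s in scheme.subunits]
    states = list(itertools.product(*[range(m + 1) for m in mults]))
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for s in states:
        i = index[s]
        for j, (k, m) in enumerate(zip(s, mults)):
            if k < m:  # one more subunit of type j turns on
                up = list(s)
                up[j] += 1
                Q[i, index[tuple(up)]] += (m - k) * alphas[j]
            if k > 0:  # one subunit of type j turns off
                dn = list(s)
                dn[j] -= 1
                Q[i, index[tuple(dn)]] += k * betas[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    open_index = index[tuple(mults)]
    return MarkovExpansion(states=states, rate_matrix=Q, open_state_index=open_index)


def stationary_distribution(expansion: MarkovExpansion) -> np.ndarray:
    """Stationary distribution of the generator (null space of Q^T), normalized."""
    Q = expansion.rate_matrix
    w, v = np.linalg.eig(Q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


# ---------------------------------------------------------------------------
# Built-in schemes
# ---------------------------------------------------------------------------


def _hh_na() -> ChannelScheme:
    """Squid-axon Na+ channel: three m activation gates and one h inactivation gate."""
    return ChannelScheme(
        name="hh_na",
        subunits=(
            SubunitSpec("m", 3, _HH_RATES["m"]),
            SubunitSpec("h", 1, _HH_RATES["h"]),
        ),
        gamma=20.0,
        e_rev=50.0,
    )


def _hh_k() -> ChannelScheme:
    """Squid-axon delayed-rectifier K+ channel: four n activation gates."""
    return ChannelScheme(
        name="hh_k",
        subunits=(SubunitSpec("n", 4, _HH_RATES["n"]),),
        gamma=20.0,
        e_rev=-77.0,
    )


# CA1 pyramidal-cell channels. The upstream somatic kinetics are not expressed
# in the three rate forms used here; these built-ins are explicit
# approximations: logistic-equivalent exponential rate pairs whose midpoints
# and slopes reproduce the qualitative somatic behavior (low resting open
# probability, K-dominated resting conductance) and whose resting balance with
# the published leak densities gives a -65 mV resting potential.


def _gate(v_half: float, slope: float, rate0: float) -> RatePair:
    """Exponential rate pair giving x_inf = 1/(1+exp(-(V-v_half)/slope)).

    Negative slope yields an inactivation gate. rate0 sets the kinetic speed:
    tau(v_half) = 1/(2*rate0) ms.
    """
    return RatePair(
        alpha=_exp(rate0, -v_half, -2.0 * slope),
        beta=_exp(rate0, -v_half, 2.0 * slope),
    )


def _ca1_na() -> ChannelScheme:
    """CA1 Na+ channel (approximate): fast m^3 activation, slower h inactivation."""
    return ChannelScheme(
        name="ca1_na",
        subunits=(
            SubunitSpec("m", 3, _gate(v_half=-30.0, slope=7.0, rate0=3.0)),
            SubunitSpec("h", 1, _gate(v_half=-45.0, slope=-4.0, rate0=0.06)),
        ),
        gamma=20.0,
        e_rev=55.0,
    )


def _ca1_kdr() -> ChannelScheme:
    """CA1 delayed-rectifier K+ channel (approximate): one slow activation gate."""
    return ChannelScheme(
        name="ca1_kdr",
        subunits=(SubunitSpec("n", 1, _gate(v_half=13.0, slope=9.41, rate0=0.1)),),
        gamma=20.0,
        e_rev=-90.0,
    )


def _ca1_ka() -> ChannelScheme:
    """CA1 A-type K+ channel (approximate): fast activation with inactivation."""
    return ChannelScheme(
        name="ca1_ka",
        subunits=(
            SubunitSpec("a", 1, _gate(v_half=11.0, slope=8.0, rate0=0.6)),
            SubunitSpec("l", 1, _gate(v_half=-56.0, slope=-8.0, rate0=0.04)),
        ),
        gamma=20.0,
        e_rev=-90.0,
    )


BUILTIN_SCHEMES = {
    "hh_na": _hh_na,
    "hh_k": _hh_k,
    "ca1_na": _ca1_na,
    "ca1_kdr": _ca1_kdr,
    "ca1_ka": _ca1_ka,
}

_REGISTRY = dict(BUILTIN_SCHEMES)


def get_scheme(name: str) -> ChannelScheme:
    """Look up a registered channel scheme by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise UnknownSchemeError(name) from None
    return factory()


def register_scheme(name: str, factory: Callable) -> None:
    """Register a user-defined scheme factory under a name."""
    _REGISTRY[name] = factory
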