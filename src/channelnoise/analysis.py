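"""Post-hoc analysis of simulated traces: spike detection, spike-triggered
average (STA) population currents, depolarizing-change dominance curves, and
spectral estimation.

Sign conventions: traces record population currents as gamma*(V-E)*open
(outward positive). STA deltas are reported in that recorded convention;
the dominance comparison is made on the *depolarizing* change
``-(I_x - I_x_rest)``, so "K exceeds Na" means the K+ fluctuation is
depolarizing the membrane more than the Na+ fluctuation at that lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .simulator import (
    SpikeTrain,
    Trace,
    DEFAULT_REFRACTORY,
    DEFAULT_THRESHOLD,
)

__all__ = [
    "STAResult",
    "DominanceCurve",
    "EmptyResultError",
    "detect_spikes",
    "sta_currents",
    "dominance_fraction",
    "estimate_psd",
]


class EmptyResultError(RuntimeError):
    """No usable spikes for the requested spike-triggered analysis."""


@dataclass
class STAResult:
    """Spike-triggered averages at lags (ms) *before* the spike.

    ``mean[name][k]`` is the average recorded current of that population at
    ``lags[k]`` ms before a spike; ``delta`` subtracts the population's
    resting current (mean over spike-free epochs)."""

    lags: np.ndarray
    mean: dict
    delta: dict
    n_events: int


@dataclass
class DominanceCurve:
    """Per-lag fraction of spikes in which the K+ depolarizing change exceeds
    the Na+ depolarizing change (ties count as not exceeding)."""

    lags: np.ndarray
    fraction: np.ndarray


def detect_spikes(trace: Trace, threshold: float = DEFAULT_THRESHOLD,
                  refractory: float = DEFAULT_REFRACTORY) -> SpikeTrain:
    """Upward threshold crossings of the voltage trace honoring a refractory period."""
    V = np.asarray(trace.V)
    crossings = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    times = []
    last = -math.inf
    for i in crossings:
        t = trace.t0 + i * trace.dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return SpikeTrain(times=np.asarray(times), threshold=threshold, refractory=refractory)


def _resting_currents(trace: Trace, spikes: SpikeTrain, guard: float = 50.0) -> dict:
    """Per-population mean current over spike-free epochs (no spike within +/-guard ms)."""
    t = trace.t
    quiet = np.ones(len(t), dtype=bool)
    for ts in spikes.times:
        quiet &= (t < ts - guard) | (t > ts + guard)
    if not quiet.any():  # densely spiking trace: fall back to the full mean
        quiet[:] = True
    return {name: float(np.mean(I[quiet])) for name, I in trace.currents.items()}


def _event_matrix(trace: Trace, spikes: SpikeTrain, window: float):
    """Indices of usable spikes and the lag grid (0..window, step dt)."""
    n_lags = int(round(window / trace.dt)) + 1
    lags = trace.dt * np.arange(n_lags)
    idx = np.round((spikes.times - trace.t0) / trace.dt).astype(int)
    usable = idx[idx >= n_lags - 1]
    if len(usable) == 0:
        raise EmptyResultError("no spikes far enough from the trace start for this window")
    return usable, lags


def sta_currents(trace: Trace, spikes: SpikeTrain, window: float = 10.0) -> STAResult:
    """Average per-population current at each lag before the detected spikes.

    Spikes closer than ``window`` to the trace start are dropped. ``delta``
    is relative to the spike-free resting current.
    """
    usable, lags = _event_matrix(trace, spikes, window)
    rest = _resting_currents(trace, spikes)
    offsets = np.round(lags / trace.dt).astype(int)
    mean = {}
    delta = {}
    for name, I in trace.currents.items():
        samples = I[usable[:, None] - offsets[None, :]]  # (events, lags)
        m = samples.mean(axis=0)
        mean[name] = m
        delta[name] = m - rest[name]
    return STAResult(lags=lags, mean=mean, delta=delta, n_events=len(usable))


def dominance_fraction(trace: Trace, spikes: SpikeTrain, window: float = 10.0,
                       pop_k: str = "hh_k", pop_na: str = "hh_na") -> DominanceCurve:
    """Fraction of spikes whose K+ depolarizing current change strictly exceeds
    the Na+ depolarizing change, per lag before the spike.

    Depolarizing change is -(I - I_rest) in the recorded outward-positive
    convention; ties count as not exceeding, so identical series give 0.
    """
    usable, lags = _event_matrix(trace, spikes, window)
    rest = _resting_currents(trace, spikes)
    offsets = np.round(lags / trace.dt).astype(int)
    dep = {}
    for name in (pop_k, pop_na):
        I = trace.currents[name]
        dep[name] = -(I[usable[:, None] - offsets[None, :]] - rest[name])
    frac = np.mean(dep[pop_k] > dep[pop_na], axis=0)
    return DominanceCurve(lags=lags, fraction=frac)


def estimate_psd(series, dt: float, segment_length: int, overlap: float = 0.5):
    """Averaged-periodogram (Welch, Hann window) spectral density estimate.

    Returns (freqs Hz, one-sided density) normalized so that the integral
    over f >= 0 recovers the series variance (Parseval), matching the
    convention of the analytic Lorentzian spectra.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2 * segment_length:
        raise ValueError(f"series length {len(x)} < 2 x segment_length {segment_length}")
    fs = 1e3 / dt  # Hz
    f, P = welch(x, fs=fs, window="hann", nperseg=segment_length,
                 noverlap=int(round(overlap * segment_length)), detrend="constant")
    return f, P
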