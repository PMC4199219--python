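# Methods

## Model

A single isopotential membrane patch of area A (μm²) with capacitance
density C_m (μF/cm²) obeys

    C dV/dt = −Σ_x g_x(t)(V − E_x) − g_leak(V − E_leak) + I_inj

where each voltage-gated population x consists of N = round(ρ_x A)
identical channels of single-channel conductance γ_x. A channel is built
from independent two-state subunits ("gates") with voltage-dependent
opening/closing rates α_j(V), β_j(V) and multiplicities k_j; the channel
conducts iff every subunit copy is on. Leak channels are always
deterministic. Kinetics are evaluated at 6.3 °C as printed for the squid
axon; no temperature-scaling machinery exists because none of the supported
models uses one.

Units everywhere: mV, ms, pA, nS, pF, MΩ, μm², with γ in pS and densities
in channels/μm² (1 μF/cm² ≡ 0.01 pF/μm²; 1 pA through 1 MΩ ≡ 10⁻³ mV).

Standard models:

* `hh_membrane` — squid-axon patch: ρ_Na = 60/μm² (m³h, γ 20 pS,
  E_Na +50 mV), ρ_K = 18/μm² (n⁴, γ 20 pS, E_K −77 mV), leak 3 pS/μm²
  at −55 mV; rests at −65.16 mV.
* `ca1_membrane` — single-compartment hippocampal pyramidal-cell patch
  with Na⁺ (20/μm²), delayed-rectifier K⁺ (20/μm²) and A-type K⁺ (24/μm²)
  channels at 20 pS plus Na⁺- and K⁺-permeable leaks totalling
  0.025 mS/cm². The upstream somatic rate equations are not expressible in
  this package's three rate-function forms, so these channels are
  *approximations*: logistic-equivalent exponential rate pairs with
  literature-scale midpoints, slopes and speeds. One free parameter (the
  Kdr activation slope, 9.41 mV) was set so that the model with the
  published leak densities rests at −65 mV, which is the constraint the
  original model was tuned to. Quantities derived from the CA1 built-ins
  are therefore qualitative.

## Stochastic gating scheme

The population state of each stochastic channel type is a count vector over
the aggregated per-channel subunit-on-count states (5 states for n⁴, 8 for
m³h). Per time step and per subunit type the *exact* two-state transition
probabilities over dt are used,

    P(off→on) = α/(α+β)·(1 − e^(−(α+β)dt)),   P(on→off) = β/(α+β)·(1 − e^(−(α+β)dt)),

compounded into an (m+1)×(m+1) on-count transition matrix (convolution of
the stay-on and flip-on binomials) and Kronecker-multiplied across subunit
types. Channels are redistributed by one multinomial draw per occupied
state. This is the classic fixed-δt binomial-update scheme with the
first-order probabilities α·δt replaced by their exact two-state values —
identical to O(δt²) and unconditionally stable, so a rate spike during the
action-potential upstroke cannot produce negative probabilities.

Voltage advances by exponential Euler with conductances frozen per step
(exact for the passive membrane, stable through the stiff spike upstroke).
Deterministic populations use the continuum relaxation
x ← x + (x_∞ − x)(1 − e^(−dt/τ)) with the same macroscopic conductance
γρA·Πx^k.

Numerical choices:

* dt defaults to 0.005 ms; long stochastic runs in the test suite use
  0.01 ms, which the exact-probability update tolerates comfortably
  (subthreshold rates ≤ 4/ms give per-step probabilities ≤ 0.04).
* Rate functions are tabulated on a 0.05 mV voltage grid. Stochastic
  populations use the nearest bin (quantization ≪ sampling noise);
  deterministic populations interpolate linearly between bins so that
  small-signal (≲0.1 mV) responses remain smooth — without interpolation
  the staircase distorts measured impedances by several percent.
* Initial stochastic states are drawn from the product-binomial stationary
  law at the starting voltage; rate estimates discard a 200 ms burn-in.
* One named random stream per population, keyed by (master seed, CRC32 of
  the scheme name): switching one population's mode never perturbs the
  other populations' streams, and identical seeds give bit-identical runs.
* Spike detection: upward crossing of −20 mV with a 2 ms refractory
  period. Spikes overshoot 0 mV, so any threshold in [−30, 0] mV changes
  counts by at most a rare aborted spikelet; the suite checks this
  insensitivity.
* Resting potentials are found by scanning the steady-state current
  balance on [−90, −40] mV and polishing sign changes with Brent's method,
  choosing the root nearest −65 mV.

## Analytic noise layer

At fixed V the open count of a population is binomial, variance N p(1−p).
The single-channel open-state autocovariance is

    C₀(t) = p·Π_j (x_j∞ + (1−x_j∞)e^(−t/τ_j))^{k_j} − p²,

whose multinomial expansion is generated symbolically from the subunit
parameters: each term with per-type flip counts (q_j ≠ 0) contributes a
Lorentzian with corner f_c = (Σ q_j/τ_j)/2π and zero-frequency density
a = 4Ni²·c·τ_eff. The n⁴ and m³h printed four- and seven-term closed forms
serve as unit-test oracles for the generator. The one-sided spectral
convention is ∫₀^∞ S(f) df = variance (equivalently S(0) = 4Ni²p(1−p)τ for
a two-state scheme), and Welch periodogram estimates use the matching
scipy one-sided density, so Parseval closes without extra factors.
The per-term closed form makes the "spectral variance = binomial variance"
identity hold to rounding error, which the suite asserts at 10⁻¹⁰.

The "dominant" Lorentzian is designated in the low-open-probability sense:
every mostly-closed gate (x_∞ < ½) relaxing at full multiplicity, the
mostly-open gates contributing their steady part. For the squid-axon
schemes at rest this picks 4/(2πτ_n) ≈ 117 Hz (K⁺) and 3/(2πτ_m) ≈ 2 kHz
(Na⁺). The literal maximum-variance term for K⁺ at rest is 3/(2πτ_n)
(n_∞ ≈ 0.32 is not truly small); the field's conventional designation is
kept and the full seven/four-term sums are always used in computations.

Quasi-active impedance: the admittance is the first-order expansion of the
channel current in (δV, δx_j) with δx_j = (dx_j∞/dV)·δV/(1+i2πfτ_j),

    Y(f) = i2πf·C + g_leak + Σ_x [ ḡ_x p₀ + Σ_j ḡ_x (V₀−E_x) ∂p₀/∂x_j · (dx_j∞/dV)/(1+i2πfτ_j) ],

with dx_∞/dV by central difference (h = 1 mV/1000). Z = 1/Y. If |Y|
approximately vanishes on the grid (divergent impedance, as happens for
some CA1-like operating points) a dedicated error directs the caller to
the sine-injection estimate: inject amplitude·sin(2πft) into the
deterministic model, discard ≥4 periods + 200 ms, project the response on
the fundamental; linearity is enforced (≤2 mV excursion, second harmonic
≤5% of the fundamental). The two impedance routes agree within 0.5% for
the squid-axon model at rest; the suite requires 2%.

Voltage spectra are S_V = S_I|Z|² on a logarithmic grid (0.1–10⁵ Hz,
60 points/decade); variances integrate by trapezoid plus the analytic
S(f_end)·f_end tail of a 1/f² decay, with a grid-too-short error when the
spectrum has not begun to fall. Cross-population covariances are neglected
(independent channels, voltage frozen at V₀), which is the same small-noise
regime in which the whole linear layer is valid — the theory is expected
to fail once spontaneous spiking begins (areas ≲ 500 μm²), and the
rate-versus-area tests treat it accordingly.

## Colored-noise injection

OU current noise is generated by the exact AR(1) recursion
x' = ax + σ√(1−a²)ε, a = e^(−dt/τ), from a stationary draw, so lag-k
autocorrelations are exactly e^(−k·dt/τ) at any dt ≤ τ/10. The impedance
factor z(τ) = √∫S_unit(f)|Z(f)|²df (unit-variance OU spectrum) converts a
target voltage s.d. into the current s.d. that produces it; it is
integrated on a wide grid (10⁻³–10⁷ Hz) with an analytic near-DC
correction so very slow noise (τ up to 10⁴ ms) is handled accurately.
Calibration closes the loop in simulation within a few percent for
τ ∈ [0.1, 100] ms (the suite allows 10%).

Rate estimation under injected noise pools independent blocks, each with a
fresh stationary OU draw; for τ longer than a block the block count is
scaled up (to ≤32) so the stationary current distribution is sampled —
otherwise slow-noise rates are dominated by a handful of quasi-static
current levels. The fixed-voltage-variance experiments default to
σ_V = 5.5 mV, calibrated once so the standard 1000 μm² patch reproduces
the reported endpoints of the rate-versus-correlation-time curve
(≈40 Hz under fast noise, ≈5 Hz under very slow noise); the uncalibrated
comparison holds σ_I fixed at the τ = 1 ms calibrated value.

Channel surrogates take the binomial variance and the dominant-term
correlation time (τ_n/4 for the K⁺ scheme; the near-degenerate dominant
pair of the Na⁺ scheme reduces to τ_m/3). Collapsing a multi-Lorentzian
spectrum onto its fastest corner under-delivers voltage variance, and
spontaneous rates are exponentially sensitive to it: the K⁺ surrogate
fires at the right areas but below the K⁺-only stochastic rate, and the
Na⁺ surrogate produces far too few spikes unless its s.d. is raised ~50%.
Both mismatches are asserted as directional/order-of-magnitude properties,
not point values. The slow-noise limit ∫P(I)f(I)dI is evaluated by
quadrature of the Gaussian density against the deterministic f-I curve on
a ±4σ grid.

## What the synthetic data does and does not emulate

All test inputs are generated internally: voltage-clamp open-count series,
spontaneously spiking traces at 50–400 μm², and OU current series, at the
stated densities and kinetics. They emulate an ideal isopotential patch
with perfectly independent, identical two-state-subunit channels and
deterministic leak — no channel cooperativity, no slow inactivation
states, no spatial structure, no synaptic input, no thermal/shot noise.
Passing tests therefore validate the internal consistency of the
simulation and theory under the model's own assumptions; they do not show
that a real neuron's noise budget follows the same numbers, only that the
*method* for decomposing it is sound.

Problem sizes in the suite are chosen for seeded reproducibility at
laptop-scale runtimes: clamp statistics from 3 s at 1000 μm², rate-area
curves from 4–10 s per area over 50–400 μm², spike-triggered analysis from
12 s at 100 μm² (~100 spikes), and OU rate curves from 3–32 blocks of 2 s
per correlation time. Standard errors at these sizes are a few percent for
clamp/spectral quantities and 10–30% for the slowest-rate points, which the
test tolerances reflect.

## Known limitations

* Single compartment only; no cable or multi-compartment structure.
* Channel schemes must be products of independent identical two-state
  subunits; arbitrary Markov topologies are representable only through the
  aggregated-expansion type, and the analytic spectra require the product
  form.
* Ohmic single-channel currents (no GHK rectification), no ligand- or
  calcium-gated channels, no temperature scaling.
* The linear voltage-noise theory deliberately excludes the spiking
  regime; comparisons against simulation are restricted to areas where
  spontaneous spikes are rare.
* The CA1 built-ins are calibrated approximations (see above), suitable
  for exercising the machinery, not for quantitative claims about CA1
  pyramidal cells.
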