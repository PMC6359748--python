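# Methods

`mcchain` simulates a chain of three biological signalling media as one
communication link: a transmitter cell releases hormone bursts into fluid
(on–off keying), astrocytes transduce the absorbed hormone into cytosolic
Ca²⁺ oscillations, and the Ca²⁺ flux drives a neuron whose spike train is
relayed across an axon and a chemical synapse to a receiver that decodes
the bits.  An analytic layer computes the per-slot channel capacity and
the transmission-delay budget for the same physical constants.

Internal units are seconds, micrometres, micromolar and millivolts; the
diffusion coefficient quoted as 4.8 μm²/ms becomes 4800 μm²/s once at
config load.

## Hormonal channel

Release events are exact Dirac impulses `(time, Q0 molecules)`.  Passive
diffusion is the free-space heat kernel
`g(d,t) = (4πD_H t)^{-3/2} exp(−d²/4D_H t)`, and first-order degradation
(rate ι, default 0.2 s⁻¹) multiplies it as a survival factor — equivalent
to a decay term in the diffusion equation.  Concentrations superpose over
events, which produces the inter-slot memory: part of a pulse's tail is
still present one slot later.

The slot-capture weights `u_n` (released in slot 0, captured in slot n)
integrate `g·e^{−ιt}` over slot windows by adaptive quadrature, split at
the kernel mode for accuracy.  The raw integral has concentration units,
not probability; a capture efficiency κ maps it to a probability through
`u_n = 1 − exp(−Q0·κ·raw_n)`, so capture improves with the number of
released molecules and stays in [0, 1].  κ is calibrated once so that
`u₀ = 0.5` at the reference geometry (d = 5 μm, T = 10 s, Q0 = 5000); the
receptor cross-section that would fix κ from first principles is not part
of the model.  The weight vector is renormalised if it ever sums above 1.

The mean hormonal delay Ω_H averages the error-function first-passage
weight `erf(√(d²/4D_H ω))/√(8πD_H ω)` normalised to a density on (0, T].
The ω^{-1/2} endpoint singularity is removed by the substitution s = √ω,
after which plain trapezoid integration converges fast.  Ω_H grows
(logarithmically) with distance and (sub-linearly) with slot length.

## Astrocyte Ca²⁺ relay

The cytosol/ER exchange is a Li–Rinzel-type IP₃-receptor model: channel
flux `v_chan·m∞³n∞³h³(C_ER−C_CY)`, leak `v_leak·(C_ER−C_CY)`, Hill-2 pump
`v_pump·C²/(C²+b₃²)`, and a slow inactivation gate `dh/dt = (a₃−h)/a₂`.
All constants are the published astrocyte set (a₁ = 0.185, v_chan = 6 s⁻¹,
v_leak = 0.11 s⁻¹, v_pump = 0.9 μM/s, b₁…b₆ as printed).

Two ER sign conventions are implemented.  `as_printed` integrates the
equation set literally; it conserves `C_CY − a₁·C_ER` exactly (the two
pools rise together), which is asserted to < 10⁻⁶ μM over 100 s but does
not oscillate usefully.  `li_rinzel` (default) conserves total calcium
`C_CY + a₁·C_ER` (closed cell, default total 2 μM), the convention under
which the IP₃ window [≈0.36, 0.68] μM produces sustained oscillations
whose frequency grows with IP₃ through the lower and middle window and
plateaus near the upper boundary.  `scan_oscillation_regime` locates the
window by brute-force simulation (≥ 2 prominent peaks after a 50 s
transient in a 150 s run).

Hormone→IP₃ transduction (the G-protein receptor cascade) is a monotone
Hill map `ip3_base + (ip3_max−ip3_base)·C/(C+K_half)`.  The model does
not specify this stage quantitatively, so it is calibrated structurally:
`K_half` is pinned to the mid-slot concentration of a single pulse at the
reference astrocyte, which places a lone "1" at the Hill midpoint
(0.05 + 0.55)/2 = 0.30…0.55 μM band sweeping through the oscillatory
window.  The consequence, verified by test, is one Ca²⁺ transient per
"1" slot: "1011" yields 3 hormone waves and 3 Ca²⁺ peaks, "1111" yields
exactly 4 peaks.

Ca²⁺ reaches the neuron boundary by diffusion from the ER treated as a
point source: convolution with the 3-D heat kernel at `d_ER,B = 10` μm
and `D_Ca = 20` μm²/s.  Two physical corrections are applied: the kernel
carries a clearance factor `e^{−t/τ_c}` (τ_c = 1 s) for cytosolic
buffering/reuptake en route, which removes the nonphysical `t^{-3/2}`
tail, and the resting pump/leak equilibrium (≈ 0.056 μM, solved by root
finding) is subtracted so the neuron is driven by calcium *signal*, not
by the standing background.  The kernel is normalised to unit DC gain.

The relay delay Ω_Ca is the extra time the neuron needs for its absorbed
flux variation to match the per-astrocyte cytosolic variation of one
slot.  Demand is the mean per-astrocyte total variation over [0, T] (the
relayed signal counted once); supply is the cumulative variation of the
summed absorbed flux scaled by a capture fraction (default 1/8).  With
more astrocytes the supply rate grows while the demand does not, so Ω_Ca
falls with M_A — the parallel-relay effect.  The crossing is found by
bisection on the monotone cumulative integral.

## Neural stage

The membrane potential is the resting level (−70 mV) plus the convolution
of the summed astrocyte fluxes with a unit-mass exponential response
kernel (gain 200 mV/μM, time constant 1.8 s).  The summed instantaneous
drive saturates at 60 mV (finite receptor conductance): a stronger wave
widens the depolarisation plateau instead of deepening it, which keeps
the burst length — and hence inter-slot leakage — bounded.  Response
linearity holds below saturation and is tested there.

Firing is an inhomogeneous Poisson process sampled by thinning.  The
rate is a logistic function of V around the threshold θ₁ = −55 mV with
slope 5 mV⁻¹ — effectively a hard threshold, so the rate is ≈ λ_max
(default 18 Hz, within the studied 15–30 Hz band) while V exceeds θ₁ and
≈ 0 otherwise.  A "1" slot therefore produces a near-homogeneous burst
spanning most of its slot, and a "0" slot is silent; both properties are
what the receiver's Poissonness test expects.

Axonal propagation solves the passive cable equation by a cosine
(sealed-end) eigenfunction expansion with a global membrane-leak factor
`e^{−t/(γ_m γ_c)}`.  The printed resistances and capacitance are read in
milliseconds (τ_m = 64.1 ms; longitudinal constant 1/(γ_l γ_c) =
0.125 μm²/ms), the physiological range for membrane time constants — the
seconds reading would give a ≈ 1500 s axonal delay, incompatible with the
neural stage being the fastest link in the chain.  The series includes
the i = 0 (spatially constant) mode: a sealed cable conserves mean
depolarisation apart from the leak, the finite-difference solution
contains this mode, and without it the terminal response of a one-signed
initial bump turns negative.  The truncation (60 modes) changes nothing
at the 10⁻⁶ level after 1 ms.  The axonal delay Ω_Ax is the time-to-peak
of the terminal response magnitude for a soma-end Gaussian bump, found by
dense scan plus bounded refinement (≈ 0.44 s at the default 43.2 μm; it
grows with cable length).  Spike trains are shifted rigidly by Ω_Ax.

## Synapse

Vesicles occupy a readily releasable pool (RRP, default 8) backed by a
reserve pool (60).  A spike fuses at most one vesicle, with probability
`1 − (1−p_v)^n` at occupancy n (p_v = 0.4); vacancies refill at rate
(N_RRP − n)/τ_f (τ_f = 10–40 ms).  Released vesicles are recycled into
the reserve pool after an exponential endocytosis delay (default 0.5 s);
without recycling a 40 s message at ~20 Hz would exhaust the terminal's
68 vesicles outright.  Vesicle number is conserved exactly in both modes.
A birth–death stationary model of the same chain gives the analytic
per-spike miss probability used by the capacity layer: misses grow with
firing rate (depletion) and shrink with pool size and refill speed.

The per-vesicle release-probability map `1 − exp(−p_v λ̄ T_ref/N_RRP)`
(normalisation window T_ref = 10 ms) is kept as printed-and-corrected —
negative exponent, probability-valued, linear for small argument.  Note
it decreases with pool size, whereas every bit-level trend in the system
requires release *reliability* to increase with pool size; the chain and
capacity layers therefore use the occupancy model above, and this map
serves the vesicle-level error expressions only.

Neurotransmitter absorption is an Mˣ/G/1/K queue: batch arrivals with
exponential inter-arrival (rate σλ_b) and geometric sizes (mean 1/σ), one
server with deterministic/exponential/gamma service, capacity K, and
partial-batch acceptance on overflow (whole-batch blocking is a config
switch).  The printed closed-form blocking/wait expressions are not
re-implemented (mixed indices, undefined normalisation); the
discrete-event simulator is the normative implementation, carries
Monte-Carlo standard errors, and reproduces the M/M/1/K closed form
within 3σ when forced to unit batches and exponential service.  Little's
law and exact customer balance hold at the horizon.

Postsynaptic bumps are alpha functions `G_max (t/t_p) e^{1−t/t_p}`
(t_p = 1.5 ms) with Gamma-distributed amplitude jitter (mean 1, CV 25%),
added on their local support.

## Receiver

The waveform is sampled at τ_s = 1 ms; spikes are declared at local
maxima of an N_sam-sample windowed mean exceeding ϑ₂ = 0.2·G_max (the
printed criterion has the inequality inverted — low mean ⇒ spike — which
contradicts positive bump amplitudes; a config switch restores the
literal reading).  A slot decodes to "1" iff (a) the one-sample KS test
of inter-spike intervals against Exp(λ′), λ′ = count/T the Poisson MLE,
does *not* reject at level α, and (b) λ′ ≥ ϑ₃ (default 10 Hz, about half
the burst rate).  The KS statistic is scaled by √n against the Kolmogorov
critical value; with the rate estimated from the same data the test is
conservative (Lilliefors effect) and under-rejects — the calibration test
asserts rejection ≤ α under the homogeneous null.  An index-scaled
variant of the acceptance condition is available behind a flag.

Decode windows are shifted by a fixed synchronisation offset (2.3 s),
the relay latency of the chain: the system is time-slotted and the
receiver's clock brackets the neural response to its own slot's stimulus.
Detection imposes a ~2–3 ms dead time; at the default rates the induced
left-truncation of the interval distribution stays well below the KS
rejection threshold.

The `high_snr()` preset (strong drive, p_v = 0.9, fast refill, tight
jitter, 0.5 ms sampling, α = 10⁻³, ϑ₃ = 6 Hz) is the regime in which the
link is demonstrably error-free: 64-bit random messages decode with
BER = 0, with the worst per-slot scaled KS statistic ≈ 1.6 against a
critical value of 1.95, and runs are bit-identical under a fixed seed
(one root seed spawns labelled streams per stochastic stage).

## Capacity and delay layer

Per slot, the chain is Markov X → Y → Z (transmitted bit, hormone-relay
outcome, decoded bit).  The hormone stage uses the capture vector:
`P(Y=0|X=0) = Π(1−p·u_i)` over interfering slots and
`P(Y=1|X=1) = 1 − (1−u₀)·Π(1−p·u_i)`; with M_A astrocytes capture is
parallel, `u → 1−(1−u)^{M_A}`.  The neural stage combines the
release-stage pair (a "1" survives only if all its spikes release, with
the per-spike miss from the pool occupancy model; a "0" errs if spurious
spikes all release) and the decode-stage pair (KS false alarm α plus
Poisson counting on either side of ϑ₃).  The per-bit error expressions
are also provided exactly as printed with their prior weights; the
channel transition matrix uses the prior-free conditionals, since the
printed forms stop being conditional probabilities when a prior factor is
embedded (at certain release failure they return p instead of ≈ 1).

Mutual information is computed in bits by the relay decomposition
`I(X;Z) = I(X;Y) − I(X;Y|Z)` with the conditional term expanded in joint
entropies, and verified against direct computation from the (X, Z)
marginal to 10⁻¹⁰ bits; capacity maximises over p by grid search with
bounded scalar refinement.  Capacity work uses T = 1 s, the low end of
the studied 1–20 s range: the all-spikes-must-release error rule decays
exponentially in the spike count k = λ̄T, and at T = 10 s it drives the
true-positive rate below the false-positive floor so that the measured
information flows through an inverted channel — a regime with no
communication-engineering meaning.  At T = 1 s all parameter trends are
monotone: capacity rises with Q0, M_A, N_RRP and with faster refill, and
falls with λ̄; the optimal p sits below 0.5 (≈ 0.39 at defaults) because
the channel's asymmetry penalises "1"s.

The delay budget is Ω = Ω_H + Ω_Ca + N_N·(ω + Ω_Ax), with ω the mean
queue wait.  At the defaults the ordering is ω (≈ 13 ms) ≪ Ω_Ax ≪ Ω_H
(≈ 1 s) < Ω_Ca (a few seconds).

## What the simulation does and does not emulate

The chain reproduces the *structure* of the biology — diffusion with
degradation, IP₃-gated store release, threshold firing, stochastic
vesicle handling, finite receptor capacity — with published constants
where they exist and one-time structural calibrations where the coupling
between stages is unspecified (capture efficiency, IP₃ midpoint, firing
gain, receiver offset).  It does not model active transport, spatially
resolved intracellular Ca²⁺, gap-junction coupling between astrocytes,
conductance-based action potentials, receptor subtype kinetics, or
reuptake; and the synthetic traces contain no measurement noise beyond
the modelled stochasticity.  Error-free decoding in the high-SNR regime
is therefore a statement about the model chain under its stated
conditions, not a prediction for tissue.

## Problem sizes

Default runs use a 1 ms grid (0.5 ms at high SNR), 4–64 slots of 10 s,
three astrocytes, stiff ODE integration at rtol 10⁻⁸/atol 10⁻¹⁰ (LSODA),
queue simulations of ≥ 10⁴ arrivals, 500-replicate test calibrations, and
10⁵-particle Monte-Carlo oracles in the test suite.
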