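# Methods

## The capacitor-switch (CS) neuron model

A CS unit is a single-compartment circuit extension of the
integrate-and-fire neuron in which every part has a biological reading:

* **Capacitor C to ground** — the membrane, integrating incoming charge.
  Ground is the resting potential the ionic pumps maintain, not the
  extracellular space.
* **R_ground to ground** — the pumps: a high resistance that slowly pulls
  the membrane back toward rest (recharging after hyperpolarization,
  draining a stuck depolarization).
* **Hysteretic voltage-gated switch S** — the spike-generation machinery.
  It senses the capacitor node and closes when the potential reaches
  `V_S,upper` (the threshold, +10 V in the demonstration scale); it reopens
  only when the potential has fallen to `V_S,lower` (the
  after-hyperpolarization bound, −5 V).  An optional refractory period
  `T_S,min off` forbids re-closing for a fixed time after opening.  The
  switch is purely passive — closed poles are ideal wires.
* **Floating DC "withdraw" source** (`V_DCwithdraw`, 20 V) in series with
  the switch — the action-potential stroke.  While the unit fires, the
  output node sits at `V_cap + V_DCwithdraw` (the action potential,
  `V_threshold + 20 = 30 V`), and the capacitor is *drained* through the
  source into the output paths until it reaches `V_S,lower`.  The
  constraint `V_DCwithdraw + V_S,lower > V_S,upper` guarantees complete
  discharge even against neighbours charged near threshold.
* **Trashing path** (`R_out` to ground) — disposal of the withdrawn
  charge; **outgoing paths** (diode + resistor per target) deliver charge
  to downstream units without letting them bridge each other.

The per-event charge drawn from the capacitor is
`C_C (V_threshold − V_hyperpolarization)` (7.5 µC for the 500 nF / 15 V
demonstration set), distributed among the simultaneously open paths
according to their resistances and target potentials.  The inhibitory
variant uses a double-pole (DPST) switch whose second pole connects
*drawing paths* to the withdraw-source input: while the unit fires it
pulls charge off target capacitors and trashes it through its grounded
output path.  Drawing activity does not feed back on the unit's own firing
condition (verified by test).

## Transient simulation

Fixed-step companion-model nodal analysis (MNA), the scheme of interactive
circuit simulators.  Default step 5 µs — about 1000 steps per 200 Hz drive
period; capacitors use the trapezoidal companion (second-order; backward
Euler is available as a debugging fallback).  Voltage-defined elements
(sources, closed switch poles, conducting ideal diodes) contribute branch
currents to an augmented linear system.  Each step is re-solved under
hypothesised diode/switch conduction states until self-consistent,
starting from the previous step's assignment (cap 100 iterations; ties
resolve to blocking / retain state).  Switches toggle at most once per
step, so transition times are quantised to the step grid; a switch whose
sense potential *ended* the previous step at or above threshold closes at
the start of the next step.  Shockley diodes (saturation current
calibrated from the 805.9 mV forward voltage at 1 A, emission coefficient
2 × 25.865 mV thermal voltage) are handled by damped Newton iteration;
the companion linearization is refreshed only when the diode voltage moves
by more than 0.1 mV, which keeps the factorization cache effective.

Numerical choices: every node carries a 1 GΩ leak to ground so islands
behind open switches stay well-posed (leak currents are ~10⁻⁸ of signal
currents); the system inverse is cached between conduction-state changes
and only the right-hand side is rebuilt per step; the inner march is a
numba kernel, cross-checked bit-for-bit against a plain-Python reference
implementation of the same stamps.  The simulation is seed-free and
bit-reproducible.

Step-size error: spike *times* shift by at most about one coarse step when
dt is refined (threshold crossings are quantised), and the capacitor
overshoots the threshold/hyperpolarization bounds by one step's worth of
charging.  For the 500 nF demonstration unit at dt = 5 µs this overshoot
is visible (the published traces show the same artifact); quantitative
charge accounting is therefore checked at dt = 10 ns, where the withdrawn
charge matches `C (V_th − V_hyp)` to < 0.5 %.

## Single-unit fire patterns

Four testbench variants (one excitatory unit behind a diode + `R_input`
from a square-pulse source, demonstration value set: 20 V, 200 Hz, 5 %
duty, R_input 6 Ω, C 500 nF, R_ground 1 kΩ, R_out 10 Ω):

* **regular** — one spike per 5 ms period (steady 200 Hz output);
* **slow integration** — `R_input = 80 Ω` and `C = 6 µF`: a single 250 µs
  pulse cannot reach threshold, several pulses accumulate per spike.  (The
  raised capacitance is essential: with 500 nF the charging time constant
  `C·(80‖1000) ≈ 37 µs` reaches threshold within the first pulse no matter
  the resistance, so "slow integration" is unobtainable by resistance
  alone.)
* **bursting** — `C = 6 µF`, 80 Hz / 20 % duty drive, lower bound raised
  to +8 V and a 0.5 ms switch refractory: each pulse sustains a train of
  spikes spaced by the refractory period;
* **adaptation** — three 200 Hz sources phase-shifted 120°, with the first
  path's resistance growing from 10 Ω by 30 Ω after every spike
  (`R_input,2,3 = 250 Ω`, `C = 6 µF`): interspike intervals lengthen
  monotonically.

Power-law scalings: multiplying all resistances by k and dividing all
capacitances by k preserves every node voltage; multiplying all source and
threshold voltages by k preserves the spike-time sequence exactly (the
circuit is piecewise linear and ideal diodes are scale-free).  Both are
verified numerically; the voltage scaling by 0.5 is bit-exact because the
factor is a power of two.

## The five-unit oscillator

Three excitatory units (N3, N4, N5) and two inhibitory units (N1, N2).
The wiring implemented here follows the published description in prose:
the central unit N3 drives the excitatory chain N3→N4→N5→N3 (positive
feedback) and excites N1; N1 draws charge off N3 (negative feedback); N1
and N2 inhibit each other; independent pulse sources (15 V, 5 % duty)
drive N2, N3 (200 Hz) and N5 (223 Hz in the flagship chaotic
configuration) through 10 Ω inputs.  Each unit: C = 6 µF, bounds +10/−5 V,
withdraw 20 V, R_ground 1 kΩ, R_out 10 Ω.  Optional "back synapses"
(diode + R_i,i from each unit's output to its own capacitor) and the four
ablation groups (back synapses, R_ground paths, trashing paths, the
N4/N5 chain) are switchable per configuration; a catalog of 23 benchmark
configurations covers the published frequency/ablation grid.

**Inter-unit resistances are a synthetic stand-in.**  The original circuit
drawing carrying the R_i,j values was not available as data.  The packaged
defaults were fixed once: 20 Ω for excitatory and recurrent paths (the
scale of the stated R_input/R_out) and 100 Ω for inhibitory drawing paths.
The weaker inhibition implements the published structural rule that chaos
requires the *positive-feedback* frequency mismatch — with equally strong
drawing paths, a mismatch confined to the inhibitory branch already
produces aperiodic patterns, which the published grid excludes.  Any value
can be overridden via `NetworkConfig.couplings`.

Known limitations of the reconstruction: configurations that remove both
discharge sinks (trashing paths *and* R_ground) leave the withdrawn charge
with no path to ground in this wiring, so those catalog rows go silent or
lock up instead of firing as published — the real drawing evidently
contains a drain this reconstruction lacks.  Quantitative D2 values for
ablated rows inherit the resistance guesses; the flagship full circuit
reproduces the published D2 closely, the no-R_ground rows reproduce the
published *ordering* (D2 rises when R_ground is removed) but
underestimate its magnitude.

## Correlation-dimension (D2) estimation

The fire pattern at N3 (spike = switch closure; ISIs in integer steps;
first 10 ms discarded as transient) is normalized by its maximum interval
and embedded in sliding windows of W = 23 consecutive ISIs — W ≥ 2N + 1
for the oscillator's state dimension N = 11 (five capacitor charges, five
switch states, global time).  Two pair statistics over random index pairs
(default 10⁶, seeded; exhaustive double loop when the pair budget covers
all pairs, which makes small inputs exact):

* correlation sum `C(r) = P(‖x_i − x_j‖ ≤ r)`, D2 = slope of ln C vs ln r,
  r log-spaced on [10⁻³, 10⁰] (50 points);
* rotational spectrum `S(Ω) = E exp(−½(Ω‖x_i − x_j‖)²)`, D2 = slope of
  −ln S vs ln Ω, Ω log-spaced on [10⁰, 10³].

The regression uses the central 60 % (by position) of the *informative*
grid points: values strictly inside (0, 1) and above a resolution floor of
3/n_pairs, below which a Monte-Carlo estimate reflects fewer than ~3
expected pairs and the finite-sample tail rather than the scaling law.
The fit reports the OLS slope, its Student-t 90 % confidence interval, R²
and the slope-nonzero p-value.  A *chaotic* verdict requires all of:
D2 ≥ 0.03 (smaller estimates are treated as zero), a significantly
non-zero slope (p < 0.05), an informative region spanning at least one
decade of the grid, and R² ≥ 0.9.  The last two guards matter for
discrete data: a periodic orbit whose spike times carry step-quantisation
jitter (e.g. a 223 Hz drive, whose period is not an integer number of 5 µs
steps) embeds into a handful of clustered vectors whose staircase-shaped
curve yields a small but statistically "significant" slope with a
plateau-dominated fit; requiring an actual power law over a real scaling
range rejects it, while every genuine dimension fit observed here has
R² ≥ 0.94 (the published fits report ≥ 0.99).  Natural logarithms are
used internally.

Validation uses synthetic sets of known dimension: a constant series (0),
uniform points on a segment (1) and on a 2-D patch (2) embedded in
[0,1]²³, and a quasiperiodic ISI series generated by an irrational circle
rotation (the beat phase of two incommensurate drive frequencies advances
by a fixed irrational increment per spike; its delay embedding is a closed
curve, dimension 1).  Both estimators recover these within ±0.1 (±0.2 for
the 2-D patch) at 10⁴ points and 10⁵ pairs.  These fixtures exercise the
estimators, not the simulator: passing them says nothing about whether a
particular circuit is chaotic.

## Problem sizes

The published experiments record 3000 s of simulated time (≥ 6·10⁵
intervals).  The packaged tests and the acceptance script use shorter
windows chosen as the package's own desk scale: 30–150 s of simulated
time (6–30·10³ intervals), where the D2 estimates of the benchmark
circuits are stable to within a few hundredths, and 10⁵–3·10⁵ sampled
pairs.  The full durations remain available through the library and the
`cs-neuron tables --duration 3000` command.
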