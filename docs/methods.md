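# Model and methods

## Neuron models

Striatal neurons use the multi-timescale adaptive threshold (MAT) model:
a leaky membrane `tau_m dV/dt = -V + R I` that is **not** reset at spikes,
with a dynamic threshold `theta(t) = omega + h1(t) + h2(t)` where each
`h_j` jumps by `alpha_j` at a spike and decays with `tau_th_j`. A spike is
emitted when `V >= theta` outside a 2 ms dead time. Shared constants are
the published ones: `tau_m = 5 ms`, `R = 50 MOhm`, `tau_th1 = 10 ms`,
`tau_th2 = 200 ms`, refractory 2 ms. Resting thresholds keep their
published intrinsic-bursting (MSN, `omega = 26 mV`) and fast-spiking
(FSI, `omega = 11 mV`) values; the kernel amplitudes are calibration
constants (below). The MAT rheobase is exactly `omega / R` (520 pA for
MSNs, 220 pA for FSIs) because the non-resetting membrane converges to
`V_inf = R I`.

Cortical input neurons are leaky integrate-and-fire units with
exponential post-synaptic currents: `tau_m = 10 ms`, `R = 50 MOhm`,
threshold 15 mV, reset 0 mV, refractory 2 ms.

Synapses are exponential current pulses (decay 2 ms excitatory, 5 ms
inhibitory) with a uniform 1 ms conduction delay. Intra-striatal synapses
are inhibitory, cortico-striatal ones excitatory. Integration is forward
Euler at `dt = 0.1 ms` with exact exponential decay of the synaptic,
threshold and liquid-state variables; a dt-halving test bounds the
first-spike-time error below one step.

## Circuit

500 MSNs and 50 FSIs are placed i.i.d.-uniformly on a 1 mm x 1 mm torus.
Connectivity: FSI->MSN within 100 um with probability 0.74; MSN->MSN with
the Gaussian profile `p(d) = 0.2 e^{1/2} e^{-d^2/(2 sigma^2)}`
(`sigma = 0.2 mm`, so `p(sigma) = 0.2` exactly); no MSN->FSI or FSI->FSI
synapses. Every striatal neuron receives a fixed random 25% of the 50
cortical neurons (12 sources, floor rounding). Weights are drawn
uniformly per edge type and multiplied by the global factors `w_s`
(intra-striatal), `w_c` (cortico-striatal) and an extra constant on
cortex->FSI.

## Position encoding

The agent position on the unit square is coded by 25 neurons per axis
with preferred coordinates on a uniform grid. Neuron `i` receives
`i_max * exp(-(i - u)^2 / (2 sigma_idx^2))` pA where `u` is the position
in fractional grid-index units; the profile is clipped at the boundaries
(the task plane is not periodic). Each cortical neuron additionally
receives an independent Poisson event train. The peak DC is deliberately
*sub*-threshold (`i_max = 1.2 x` rheobase is reached only exactly at the
peak; effective drive elsewhere is lower) so that cortical firing remains
irregular: a strongly supra-threshold LIF fires periodically at beta-band
intervals and the striatum then phase-locks to it, which corrupts every
downstream ISI statistic. The background is therefore dense and weak
(600 events/s at 60 pA) rather than the sparser train used in the
single-neuron demonstration protocol (150 events/s).

## Calibration of the free constants

The spatial rules, population counts, scale-factor semantics and analysis
definitions above are fixed; the per-synapse base weight ranges, the
threshold-kernel amplitudes and the encoder constants are free and were
calibrated once against the target activity statistics at the reference
configuration `{w_s=18, w_c=113}` (MSN mean rate near 4 spikes/s with a
broad rate distribution, CV mode near 2, episodic FSI gamma bursts) and
the mean-rate responses of the two alternative configurations
`{18, 165}` and `{0, 113}` (near 14 and 8 spikes/s). The committed
values:

| constant | value |
|---|---|
| base weight range, cortex->MSN and cortex->FSI | U(0, 20.2) pA |
| base weight range, FSI->MSN | U(4, 12) pA |
| base weight range, MSN->MSN | U(3.25, 9.75) pA |
| cortex->FSI extra factor | 0.35 |
| MSN threshold kernel (alpha1, alpha2) | (30, 4) mV |
| FSI threshold kernel (alpha1, alpha2) | (4, 2) mV |
| encoder i_max / sigma_idx | 432 pA / 2.0 index units |
| encoder Poisson background | 600 events/s x 60 pA |

The MSN `alpha1` is much larger than the published intrinsic-bursting
value (1.7 mV): with the large coincidence-driven synaptic fluctuations
of this circuit, the published amplitude lets the non-resetting membrane
ride above threshold and fire at the refractory ceiling, producing >50%
gamma-band ISIs. The committed amplitude suppresses these runaway bursts
while leaving episodic firing intact. The small FSI factor (0.35) keeps
interneurons position-selective — they fire gamma-band bursts when the
agent enters their input field rather than tonically at >100 spikes/s.

Measured at the committed configuration (100 s protocol, three circuit
realizations): mean MSN rates ~5.3 / ~10.2 / ~7.4 spikes/s at
`{18,113}` / `{18,165}` / `{0,113}`, CV mode 2.0, top-5-FSI gamma ISI
share ~35%.

**Known limitation — ISI band composition.** At the reference
configuration the model's MSN ISI mass sits mainly in the beta/gamma
bands (slow/delta share ~19%), whereas striatal recordings place ~3/4 of
ISIs above 250 ms. Within this model family the slow/delta share and the
mean-rate triplet are in direct tension: every regime we found with a
slow-dominated ISI distribution (strong slow threshold adaptation, or
slow integrated inhibition acting as a winner-less-competition memory)
clamps the population rate near 2-3 spikes/s and removes nearly all
sensitivity to `w_c`, destroying the 4 -> 14 spikes/s response to
stronger cortical drive. The published circuit presumably resolves this
with synaptic/weight details that are not in the main text. The
band-composition checks in the acceptance suite document this miss
explicitly rather than hiding it.

## Random-trajectory statistics protocol

Activity statistics are measured while the encoded position jumps to a
new uniformly random location every 300 ms for 100 s of simulated time.
Per MSN: rate = count / duration; CV = population-std(ISI)/mean(ISI)
(neurons with fewer than 3 spikes are excluded); CV2 over adjacent ISI
pairs, `|ISI_{n+1} - ISI_n| / (ISI_{n+1} + ISI_n)` (N-2 values for N
spikes — the N-1 ISIs yield N-2 adjacent pairs). Histograms use bin
widths 0.5 (CV, centered on multiples of 0.5 so the reported mode is
itself a multiple of 0.5), 0.05 (CV2), 1.2 s (ISI) and 0.1 in log10
space (rate). ISI bands are half-open: gamma (0, 30], beta (30, 80],
theta-alpha (80, 250], slow/delta (250, inf) ms; band percentages are
ISI-count-weighted and averaged over neurons with at least one ISI.

## Liquid state, separation, edge of chaos

The liquid state is the exponentially filtered spike train
`ds_j/dt = -s_j/tau0 + (1/tau0) sum delta(t - t_j^f)` with `tau0` read in
SI seconds (default 0.02 s): traces are instantaneous rate estimates in
spikes/s and the impulse response integrates to one spike regardless of
`tau0`. Readouts and all separation measurements share the same `tau0`.

Separation between two runs is the Euclidean distance between their
liquid-state vectors, sampled on the integration grid (curves are
reported at 1 ms resolution). The separation experiment drives the same
circuit from identical initial conditions and identical background
realizations with two encoded positions a fixed distance apart (1/100,
1/10 or 1/5 of the environment width) and averages the cortical-level and
striatal-level distances over 5 circuit instantiations x 5 position
pairs.

The edge-of-chaos analysis perturbs a run by one extra cortical spike:
at t = 50 ms one randomly chosen cortical neuron is lifted over threshold
so the extra spike propagates synaptically *and* shifts that neuron's own
subsequent firing. A configuration is chaotic when ln of the 50 ms
moving-average separation exceeds 0 at every sample from 200 ms after the
perturbation to the end of the run; an identically zero curve is ordered.
On the default grid the frontier lies between `w_c = 90` and `w_c = 113`
for `w_s` in {0, 18}, with the reference configuration just inside the
chaotic side.

## Tasks and readouts

Three target functions map agent state to a 4-vector over the cardinal
directions (E, W, N, S; rectification preserves the Euclidean norm, so
unit step targets stay unit vectors):

- **GOAL** — unit steps toward the center of the plane; the agent is
  teleported to a random position every 10 steps and otherwise moves by
  the advocated action (step size 1/50 of the environment, clipped at the
  boundary).
- **MG5 / MG15** — the discretized delay system
  `dy_i = 0.2 x_i / (1 + (x_i/15)^{10}) - 0.1 y_i`, `dx_i = y_{i-tau} - x_i`
  with `x_0 = y_0 = 0.5` and the history primed at 0.5. The (x, y) orbit
  is mapped affinely into the central 80% of the plane (bounding box from
  a 10^4-step reference orbit); the target at step i is the rectified
  scaled increment. The agent's positions follow the orbit itself for
  the entirety of training and testing — the trajectory is generated by
  the equations, not by the readout. Larger delays couple the target to
  older inputs and demand more fading memory. The delay of the harder
  task is 15 steps (one passage of the source text says 23; the figures
  and the task comparison consistently use 15, and the delay is
  configurable).

Four perceptrons read the striatal liquid state. Per 300 ms step: wait
50 ms at the position, advocate `a = W s(t+50)`, accumulate
`dW = sum_{k=1..50} lr (r/|r| - a/|a|) s(t + 50 + 0.1k)^T` over the next
5 ms, wait the remaining 245 ms, then move. A zero-norm `a` or `r`
normalizes to the zero vector, so the untrained readout scores exactly
1.0 on unit targets. The learning rate (0.01) only sets the weight
scale — the normalized error makes the direction dynamics invariant to
it. Readout learning is strictly downstream and never alters the
circuit.

Performance is the test-phase average of `|r/|r| - a/|a||` (0 best, 2
worst). Generalization compares `a` with the action advocated by a twin
network whose agent sits a slightly shifted position (distance ~
N(4, 4/3) um at a uniform angle, with the environment read as 1000 um);
the twin starts from the trained network's state and sees an identical
background realization.

## Problem sizes and determinism

Default experiment sizes: 100 s statistics runs (the test suite uses one
realization, the acceptance script three), 300 training steps with a
30-50 step test phase for the scaled-down learning checks (the full
protocol of 3000 steps is the configurable default of
`TrainingSchedule`), 500-700 ms runs for separation and perturbation
curves. Every stage is bit-reproducible from its seed: circuit
generation, background realizations, agent resets and generalization
shifts all derive from `numpy.random.default_rng` streams, and the
simulation kernel is deterministic. The synthetic protocols emulate the
study conditions (random position resampling, Poisson background); they
do not emulate structured cortical correlations, neuromodulation, or
plasticity of the circuit itself, so passing tests speak to the model's
internal consistency, not to fidelity against in-vivo recordings.
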