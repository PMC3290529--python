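# Methods

## Membrane model

Each unit is an Izhikevich two-variable neuron

    dv/dt = 0.04 v² + 5 v + 140 − u + I / C
    du/dt = a (b v − u)
    if v ≥ v_peak: v ← c, u ← u + d

with the phasic-bursting constants a = 0.02 /ms, b = 0.25, c = −55 mV,
d = 0.05, v_peak = 30 mV, C = 1. Voltages are in mV, time in ms.
Integration is forward Euler at dt = 0.2 ms; both derivatives are
evaluated at the pre-update state (simultaneous Euler), the threshold is
tested on the updated voltage, and the reset is applied before the next
step, so a spiking neuron always reports v = c exactly. Spike counts at
this dt are sensitive to the update order, which is why it is fixed and
tested; halving dt changes the step-response count by at most one spike.

Initial state: v₀ = −64 mV, u₀ = b·v₀ = −16 for every neuron. This is
(within 0.5 mV) the resting equilibrium of the parameter set, and it is
the only initialization consistent with the model's baseline
requirement that undriven neurons stay silent indefinitely: any u₀
below ≈ −16.25 lies under the minimum of the zero-input v-nullcline, so
the cell fires spontaneously regardless of v₀.

This parameter set is deliberately marginal — that is what makes it
phasic. Its static saddle-node sits at I ≈ 1.016, the post-reset point
(c, u) lies almost exactly on the v-nullcline fold, and bursts
self-terminate as u creeps past the margin. Several design choices
below exist to keep measurements off this knife edge.

## Drive calibration

The stimulus current per active pixel is w_input = 2.4 (config field
`w_input`; the high-contrast condition multiplies it by 3, preserving a
3:1 contrast ratio between conditions). The value is a calibration with
three simultaneous requirements:

1. a driven layer-1 neuron responds to the figure-ground texture with a
   transient burst of exactly 12 spikes in the first 50 ms
   (240 spikes/s) at dt = 0.2 ms;
2. undriven neurons remain silent (see above — this rules out reaching
   the 12-spike burst by depolarizing the initial state instead);
3. the OFF population, driven by the negative image of the stimulus,
   is hyperpolarized deeply enough that stimulus removal triggers a
   rebound burst (a sustained drive of −1 produces no rebound at these
   parameters; −2.4 does, for stimuli of 25 ms and longer).

A unit drive (w = 1) fails requirements 1 and 3: it yields at most 8–9
spikes in 50 ms from any silent initial state, and no OFF rebound. Both
w_input and (v₀, u₀) are exposed in the configuration.

## Network

Two feature channels × two N×N layers (N = 64 by default; the figure is
the centred 16×16 block). Excitatory connections are retinotopic with
receptive-field size one: stimulus → layer 1 (weight w_input) and
layer 1 → layer 2 (weight w_exc = 400). Layer 1 receives no inhibition.
Layer 2 additionally receives pooled inhibition

    w_inh · (Σ_kl S₁,kl / N²) · 𝟙,    w_inh = −700,

a spatially constant term proportional to the population mean of the
source layer's spike activity — full-field surround inhibition.
Layer 2 reads the layer-1 spike map of the previous Euler step (one-dt
transmission delay, the minimal causal choice).

Wiring modes:

* `figure_ground` — each channel's layer 2 listens only to its own
  layer 1. The two channels carry a texture and its complement.
* `on_off` — layer 2 integrates excitation and pooled inhibition from
  both channels' layer 1. The channels are the ON and OFF populations
  of one feature: ON layer 1 is driven by +w·frame while the stimulus
  is on, OFF layer 1 by −w·frame, so that removal releases OFF into a
  rebound burst. (The alternative of a rectified temporal-derivative
  pulse was considered; the signed-drive form was kept because it uses
  the rebound property the neuron model is chosen for.)

## Inhibition kinetics

Excitation is pulsatile: a presynaptic spike contributes to the
excitatory term only on the step after it fires. The pooled inhibitory
signal, in contrast, is a low-pass trace: each step's population spike
fraction is added to a trace that decays exponentially with
`inh_tau_ms` = 2 ms (0 recovers strictly pulsatile inhibition).

This asymmetry is a deliberate model assumption (inhibitory synaptic
currents are slower than AMPA-type excitation) and it is load-bearing.
With strictly one-step inhibition, an inhibitory volley can veto an
excitatory kick only if both land on the same 0.2 ms step; stimulus
cohorts whose onsets differ by a few ms then never interact, and
masking collapses into a fragile pattern of exact step coincidences
(non-monotone masking curves, rebound spikes at the centre in the
mask-only condition). The 2 ms trace makes the pooled inhibition span
the interval between presynaptic volleys, which gives monotone
disappearance of the figure-ground index under pattern masking, a
silent centre under a mask alone, and a U-shaped metacontrast curve,
while leaving the unmasked figure relay (inhibition from only 6% of the
grid) untouched. Values much above 2 ms start to suppress the unmasked
relay itself; values at or below 1 ms re-enter the coincidence regime.

## Stimuli and schedules

All frames are binary N×N arrays; 1 means the pixel matches the
channel's feature preference. Generators: the figure-ground pair
(centred block + complement), Bernoulli(p = 0.5) pattern masks (the
density is a free choice — an unbiased random binary matrix — exposed
in config), the all-ones uniform mask, and the metacontrast target/mask
complement pair (disjoint supports, same feature preference).

Schedules are lists of (channel, frame, onset, duration, gain) events;
overlapping same-gain events OR pixel-wise, signed gains implement the
OFF-channel drive and contrast. SOA is onset-to-onset throughout. In
the figure-ground masking experiments the texture is shown from t = 0
until mask onset (duration = SOA) and the mask, presented to both
channels, stays on through the analysis window. Repetition masking
constrains SOA ≥ target duration, so the second target starts after the
first ends.

## Response metrics

Figure-ground metrics use the first 50 ms from stimulus onset: mean
per-neuron spike counts over the figure region and the ground region
(everything else, no border buffer), averaged over both channels; the
modulation index is the raw difference F − G; rates are
count·1000/window. Metacontrast and repetition metrics use a 100 ms
window from (second-) target onset over the central 16×16 region;
suppression is 100·(1 − masked/control). Dips are local minima of a
response curve, plateau ties broken to the smaller SOA.

Two readout decisions:

* Masked figure rates are reported for the driven channel's layer-2
  figure region (channel averaging is used for the modulation index,
  where the paper-defined quantity demands it).
* The repetition-masking headline curve reads layer 1. The effect
  itself is layer-1 burst refractoriness (the recovery variable stays
  elevated for tens of ms after the first burst), while the layer-2
  relay of a brief 256-pixel target sits exactly on the 1-vs-2
  spikes-per-kick fold of the reset dynamics and toggles between runs
  that differ by one spike; both layers are kept in the result table.

The repetition normalization control presents the identical lone target
after the network has settled (t = 150 ms), not at t = 0: the marginal
burst dynamics give ±1-spike differences between the configured initial
state and the relaxed fixed point, and the control must equal the
long-SOA limit for the normalized curve to recover to exactly 1.

## Randomness and reproducibility

The only stochastic element is the pattern mask. Each (SOA, repeat)
condition derives its seed counter-style from the master seed, so
adding SOAs to a sweep does not change existing conditions' masks, and
every run is bit-for-bit reproducible from its manifest. Everything
else — including every metacontrast and repetition quantity — is fully
deterministic.

## Problem sizes

Default sweeps are desk-scale: 64×64 grids, trials of at most ~500 ms
simulated time (≤2500 Euler steps), 7 SOAs × 20 seeds for pattern
masking, a 5 ms SOA grid over [−100, 200] ms for metacontrast, and 7
SOAs × 2 contrasts for repetition. The full acceptance computation runs
in under two minutes on one CPU; the unit suite uses reduced sweeps of
the same code paths.

## What the generators emulate — and what they do not

The synthetic stimuli reproduce the study conditions exactly (binary
feature maps, a single centred figure, complement masks), which is what
the model is about — but they are idealizations. All neurons in a
cohort are identical and noiseless, so population responses are
perfectly synchronous volleys and every regional mean is a multiple of
1/(region size); real tissue would dither the knife-edge cases (the
relay bistability, exact step coincidences) that several design
choices above work around. Passing tests therefore demonstrate the
mechanism — segregation and its masking by spatiotemporal interference
of pooled inhibition — not quantitative agreement with biological
firing rates.

## Known limitations

* No feedback, lateral, or distance-dependent connectivity: the
  inhibitory field is the entire layer, by construction.
* The metacontrast ON-response is suppressed as strongly as the OFF
  response, so maximal suppression (~83%) overshoots the ~50% expected
  when only the OFF component is vulnerable, and the dip positions sit
  at the mask transitions shifted by the OFF-rebound latency (~15 ms
  after stimulus offset) rather than exactly at target-offset
  coincidence.
* Under pattern masking at the shortest SOA the figure relay is
  extinguished rather than halved: with w_inh = −700 and p = 0.5 the
  pooled mask inhibition is strong enough to silence the layer-2 relay
  outright once it spans the inter-volley interval.
* Spike counts at dt = 0.2 ms depend on the documented update order;
  the suite pins them, and the dt-halving test bounds the drift.
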