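# spikemask

A two-layer spiking network of Izhikevich phasic-bursting neurons that
performs feedforward figure-ground segregation through pooled surround
inhibition, together with simulated visual-masking experiments: backward
masking of figure-ground textures by pattern and uniform masks,
metacontrast masking of a single target by its surrounding complement,
and repetition masking by a second identical target.

It is aimed at computational-neuroscience work on how purely feedforward
surround inhibition can both create a figure-ground signal and destroy
it when a mask follows the stimulus — no feedback or recurrent
connections are involved anywhere in the model.

## Model

Every neuron follows the Izhikevich membrane model

```
dv/dt = 0.04 v² + 5 v + 140 − u + I
du/dt = a (b v − u)
if v ≥ 30 mV:  v ← c,  u ← u + d
```

with a = 0.02, b = 0.25, c = −55, d = 0.05 — the phasic-bursting regime,
which responds to a current step with a high-frequency burst and fires
rebound bursts on release from hyperpolarization. Integration is forward
Euler at dt = 0.2 ms.

The network is two feature channels × two 64×64 layers. Binary stimulus
frames drive layer 1 retinotopically (one pixel → one neuron, no
inhibition). Each layer-2 neuron receives

```
I₂ = w_exc · S₁(t−δ)  +  w_inh · ⟨S₁⟩ · 𝟙        w_exc = 400, w_inh = −700
```

a point-to-point copy of the presynaptic spike map plus a spatially
constant inhibition proportional to the population mean of the source
layer (the inhibitory receptive field is the whole layer). The pooled
inhibition decays exponentially with a 2 ms time constant — a slow-IPSP
assumption documented in `docs/methods.md`. In the figure-ground wiring
each channel inhibits itself; in the ON/OFF wiring used for metacontrast
and repetition masking, layer 2 integrates excitation and inhibition
from both channels, where the OFF channel is driven by the negative
image of the stimulus so that stimulus removal triggers a rebound burst.

A figure-ground texture (a 16×16 central square and its complement)
makes layer-1 figure neurons fire a 12-spike burst in the first 50 ms;
layer 2 relays the burst at the figure while the large active background
silences itself through its own pooled inhibition — that asymmetry is
the figure-ground signal, summarized by the modulation index F − G
(figure minus ground mean spike counts, channel-averaged, first 50 ms).

## Worked example

```python
import dataclasses
from spikemask import ExperimentConfig, run_fg_segregation, run_fg_masking, run_repetition
from spikemask.experiments import index_curve, repetition_dip

cfg = ExperimentConfig()

seg = run_fg_segregation(cfg)
d = seg.data
l1 = d[(d.channel == 0) & (d.layer == 1) & (d.region == "figure")].iloc[0]
print(f"layer-1 figure burst: {l1['count']:.0f} spikes in 50 ms ({l1['rate']:.0f} spikes/s)")
print(f"modulation index (F - G, layer 2): {seg.controls['modulation_index_l2']:.1f}")

small = dataclasses.replace(cfg, fg_soas=(3.0, 10.0, 50.0), n_mask_seeds=5)
masked = run_fg_masking(small, "pattern")
print("pattern-mask modulation index by SOA:",
      {soa: round(v, 2) for soa, v in index_curve(masked).items()})

rep = run_repetition(cfg)
soa, depth = repetition_dip(rep, "normal")
print(f"repetition dip: second-target response falls to {depth:.2f} of control at SOA {soa:.0f} ms")
```

prints

```
layer-1 figure burst: 12 spikes in 50 ms (240 spikes/s)
modulation index (F - G, layer 2): 6.0
pattern-mask modulation index by SOA: {3.0: 0.5, 10.0: 1.99, 50.0: 6.0}
repetition dip: second-target response falls to 0.40 of control at SOA 30 ms
```

The driven layer-1 neurons burst at 240 spikes/s; the unmasked
figure-ground signal is 6 spikes of figure-over-ground difference; a
backward pattern mask erodes that index monotonically as the SOA
shortens (0.5 at 3 ms — segregation nearly abolished), and a repeated
target is maximally suppressed at an onset asynchrony of 30 ms.

The same sweeps are available from the shell:

```
spikemask run fg-mask --out results.csv --mask-type pattern --seed 1
spikemask report results.csv
```

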