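"""Two-channel, two-layer retinotopic spiking network with surround inhibition.

Architecture
------------
Each of two feature channels holds two N x N layers of Izhikevich
neurons.  Layer 1 is driven point-to-point by the channel's binary
stimulus field (weight ``w_input`` per active pixel) and receives no
inhibition.  Layer 2 of a channel receives, from each of its source
layer-1 populations,

    I2 = w_exc * S1  +  w_inh * (sum(S1) / N^2) * ones

where ``S1`` is the source layer's binary spike map of the *previous*
Euler step (a one-step transmission delay avoids within-step
circularity).  The excitatory term is a retinotopic copy of the spike
map; the inhibitory term is spatially constant - every layer-2 neuron is
inhibited by the pooled activity of the entire source layer, normalized
by the neuron count.  Inhibitory weights are negative.

Excitation is strictly pulsatile (one step per presynaptic spike), but
the pooled inhibitory signal is low-pass filtered: each step's spike
fraction feeds a trace that decays exponentially with ``inh_tau_ms``
(default 2 ms; 0 makes inhibition pulsatile too).  Inhibitory synaptic
currents outlasting excitatory ones is what lets the pooled surround
signal bridge the interval between presynaptic volleys; see
docs/methods.md for why this is load-bearing.

Two wirings are used:

* ``figure_ground`` - each channel's layer 2 listens only to its own
  channel's layer 1 (within-channel surround inhibition).  The channels
  represent opposite preferences for one feature (figure texture vs its
  complement).
* ``on_off`` - layer 2 integrates excitation and pooled inhibition from
  *both* channels' layer 1.  The channels are the ON and OFF populations
  of a single feature: the ON layer is driven while a stimulus is
  present, the OFF layer is driven by its negative image so that
  stimulus removal releases it into a rebound burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neuron import IzhikevichParams, SimulationClock, izhikevich_step
from .stimuli import StimulusSchedule

__all__ = ["NetworkConfig", "Network", "SpikeRaster", "assemble_current"]

LAYER1, LAYER2 = 0, 1


@dataclass(frozen=True)
class NetworkConfig:
    """Grid size, weights and wiring of the two-layer network.

    ``w_input`` is the drive per active stimulus pixel into layer 1.  The
    calibrated default of 2.4 makes a driven layer-1 neuron fire a
    transient burst of 12 spikes in the first 50 ms (240 spikes/s) at
    dt=0.2 ms, and is strong enough that the OFF population rebounds at
    stimulus offset; see docs/methods.md for the calibration.
    """

    N: int = 64
    n_channels: int = 2
    mode: str = "figure_ground"  # or "on_off"
    w_input: float = 2.4
    w_exc: float = 400.0
    w_inh: float = -700.0
    inh_tau_ms: float = 2.0
    params: IzhikevichParams = field(default_factory=IzhikevichParams)
    dt: float = 0.20

    def __post_init__(self):
        if self.mode not in ("figure_ground", "on_off"):
            raise ValueError(f"unknown wiring mode {self.mode!r}")
        if self.w_inh > 0:
            raise ValueError("inhibitory weight must be non-positive")

    def layer2_sources(self, channel: int) -> tuple[int, ...]:
        """Indices of the layer-1 populations feeding this channel's layer 2."""
        if self.mode == "figure_ground":
            return (channel,)
        return tuple(range(self.n_channels))


def assemble_current(F_sources, N: int) -> np.ndarray:
    """Sum retinotopic excitation and pooled surround inhibition.

    ``F_sources`` is a list of ``(F, w_exc, w_inh)`` with ``F`` a binary
    N x N field.  Each source contributes ``w_exc * F`` point-to-point
    plus the spatially constant ``w_inh * mean(F)`` over the whole grid.
    """
    I = np.zeros((N, N), dtype=float)
    for F, w_exc, w_inh in F_sources:
        F = np.asarray(F)
        if F.shape != (N, N):
            raise ValueError(f"source field shape {F.shape} does not match grid ({N}, {N})")
        if not np.isin(F, (0, 1)).all():
            raise ValueError("source fields must be binary")
        F = F.astype(float)
        I += w_exc * F + w_inh * (F.sum() / (N * N))
    return I


@dataclass
class SpikeRaster:
    """Binary spike occurrences per (channel, layer, step, row, col)."""

    data: np.ndarray  # bool, shape (n_channels, 2, n_steps, N, N)
    dt: float

    @property
    def n_steps(self) -> int:
        return self.data.shape[2]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt

    def spike_counts(self, channel: int, layer: int, window_ms=None) -> np.ndarray:
        """Per-neuron spike counts of one population in a half-open window [t0, t1) ms."""
        t0, t1 = (0.0, self.duration_ms) if window_ms is None else window_ms
        if t1 < t0:
            raise ValueError(f"inverted window [{t0}, {t1})")
        k0 = max(int(np.ceil(t0 / self.dt - 1e-9)), 0)
        k1 = min(int(np.ceil(t1 / self.dt - 1e-9)), self.n_steps)
        return self.data[channel, layer, k0:k1].sum(axis=0)

    def to_events(self) -> pd.DataFrame:
        """Tidy spike-event list with columns t_ms, channel, layer, row, col."""
        ch, layer, step, row, col = np.nonzero(self.data)
        return pd.DataFrame(
            {
                "t_ms": step * self.dt,
                "channel": ch,
                "layer": layer,
                "row": row,
                "col": col,
            }
        ).sort_values(["t_ms", "channel", "layer", "row", "col"], ignore_index=True)


class Network:
    """Stateful simulator of the two-layer network."""

    def __init__(self, config: NetworkConfig = NetworkConfig()):
        self.config = config
        self.reset()

    def reset(self) -> None:
        cfg = self.config
        shape = (cfg.n_channels, 2, cfg.N, cfg.N)
        self.v = np.full(shape, cfg.params.v0, dtype=float)
        self.u = np.full(shape, cfg.params.u_init, dtype=float)
        self.last_spikes = np.zeros(shape, dtype=bool)
        # pooled-inhibition trace per channel (exponentially decaying IPSP)
        self._inh_trace = np.zeros(cfg.n_channels)
        self._inh_decay = float(np.exp(-cfg.dt / cfg.inh_tau_ms)) if cfg.inh_tau_ms > 0 else 0.0
        self.step_index = 0

    def step(self, input_fields: np.ndarray) -> np.ndarray:
        """Advance every neuron by one Euler step.

        ``input_fields`` holds the signed stimulus drive per channel
        (shape (n_channels, N, N)); it is scaled by ``w_input`` into
        layer 1.  Layer 2 reads the previous step's layer-1 spike maps.
        Returns the new spike maps, shape (n_channels, 2, N, N).
        """
        cfg = self.config
        I = np.empty_like(self.v)
        I[:, LAYER1] = cfg.w_input * input_fields
        s1_prev = self.last_spikes[:, LAYER1].astype(float)
        self._inh_trace = self._inh_trace * self._inh_decay + s1_prev.sum(axis=(1, 2)) / (
            cfg.N * cfg.N
        )
        pooled = self._inh_trace
        for ch in range(cfg.n_channels):
            I2 = np.zeros((cfg.N, cfg.N))
            for src in cfg.layer2_sources(ch):
                I2 += cfg.w_exc * s1_prev[src] + cfg.w_inh * pooled[src]
            I[ch, LAYER2] = I2
        self.v, self.u, spiked = izhikevich_step(
            self.v, self.u, I, cfg.params, cfg.dt, step_index=self.step_index
        )
        self.last_spikes = spiked
        self.step_index += 1
        return spiked

    def run(self, schedule: StimulusSchedule, clock: SimulationClock | None = None) -> SpikeRaster:
        """Integrate the network over a stimulus schedule and record the raster."""
        cfg = self.config
        if clock is None:
            n_steps = int(np.ceil(schedule.end_ms / cfg.dt)) + int(100.0 / cfg.dt)
            clock = SimulationClock(dt=cfg.dt, n_steps=n_steps)
        if clock.dt != cfg.dt:
            raise ValueError("clock dt must match the network dt")
        if schedule.n_channels > cfg.n_channels:
            raise ValueError(
                f"schedule uses {schedule.n_channels} channels but the network has {cfg.n_channels}"
            )
        self.reset()
        raster = np.zeros((cfg.n_channels, 2, clock.n_steps, cfg.N, cfg.N), dtype=bool)
        for k in range(clock.n_steps):
            fields = schedule.input_field(k, cfg.dt, cfg.N)
            if schedule.n_channels < cfg.n_channels:
                pad = np.zeros((cfg.n_channels - schedule.n_channels, cfg.N, cfg.N))
                fields = np.concatenate([fields, pad], axis=0)
            spiked = self.step(fields)
            raster[:, :, k] = spiked
        return SpikeRaster(raster, cfg.dt)


def run_network(
    schedule: StimulusSchedule,
    config: NetworkConfig = NetworkConfig(),
    clock: SimulationClock | None = None,
) -> SpikeRaster:
    """One-shot convenience wrapper: build a network, run a schedule, return the raster."""
    return Network(config).run(schedule, clock)
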