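"""Binary stimulus frames and time-resolved presentation schedules.

Every visual input to the network is a binary N x N array: a pixel value
of 1 means the feature at that location matches the channel's preference,
0 means it does not.  The generators here produce the figure-ground
texture (a centred square figure plus its complement), random pattern
masks, the uniform (all-ones) mask, and the metacontrast target/mask pair
(the mask is the complement of the target, presented to the same feature
preference).

A :class:`StimulusSchedule` composes frames into per-channel input fields
over the Euler time grid.  Events carry a signed ``gain`` so that an OFF
population can be driven with the negative image of a stimulus while it
is on (hyperpolarization whose release triggers a rebound burst at
stimulus offset).  Overlapping events with the same gain on one channel
are combined by pixel-wise OR, keeping inputs binary per polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryFrame",
    "ScheduleEvent",
    "StimulusSchedule",
    "make_fg_texture",
    "make_pattern_mask",
    "make_uniform_mask",
    "make_metacontrast_pair",
    "build_schedule",
    "frame_to_pgm",
]


@dataclass(frozen=True)
class BinaryFrame:
    """An N x N array of {0,1} pixels with a role tag."""

    pixels: np.ndarray
    label: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"frame must be square 2-D, got shape {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("frame pixels must be strictly binary (0 or 1)")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def n(self) -> int:
        return self.pixels.shape[0]

    @property
    def total(self) -> int:
        """Number of active pixels."""
        return int(self.pixels.sum())

    def complement(self, label: str = "") -> "BinaryFrame":
        return BinaryFrame(1 - self.pixels, label or f"complement({self.label})")


def _centered_block(N: int, fig_size: int) -> np.ndarray:
    if fig_size >= N:
        raise ValueError(f"fig_size must be smaller than the grid (got {fig_size} >= {N})")
    if fig_size <= 0:
        raise ValueError("fig_size must be positive")
    if N % 2 or fig_size % 2:
        raise ValueError("N and fig_size must both be even so the figure centres exactly")
    px = np.zeros((N, N), dtype=np.uint8)
    lo = N // 2 - fig_size // 2
    hi = lo + fig_size
    px[lo:hi, lo:hi] = 1
    return px


def make_fg_texture(N: int = 64, fig_size: int = 16) -> tuple[BinaryFrame, BinaryFrame]:
    """Figure-ground texture: a centred figure square and its complement.

    Channel 1 prefers the figure feature (ones only inside the centred
    ``fig_size`` x ``fig_size`` block); channel 2 gets the binary
    complement, representing the opposite feature preference.  Together
    the two frames tile the grid.
    """
    feat1 = BinaryFrame(_centered_block(N, fig_size), "figure-input")
    feat2 = feat1.complement("complement")
    return feat1, feat2


def make_pattern_mask(N: int = 64, p: float = 0.5, seed=None) -> BinaryFrame:
    """Random binary pattern mask with i.i.d. Bernoulli(p) pixels."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"ones probability must lie in [0,1], got {p}")
    rng = np.random.default_rng(seed)
    px = (rng.random((N, N)) < p).astype(np.uint8)
    return BinaryFrame(px, "pattern-mask")


def make_uniform_mask(N: int = 64) -> BinaryFrame:
    """Uniform mask: every pixel active."""
    return BinaryFrame(np.ones((N, N), dtype=np.uint8), "uniform-mask")


def make_metacontrast_pair(N: int = 64, fig_size: int = 16) -> tuple[BinaryFrame, BinaryFrame]:
    """Central target and its complement as the surrounding metacontrast mask.

    The two frames have disjoint support, so the mask adds no excitatory
    drive at the target location: its influence there is purely the pooled
    surround inhibition.
    """
    target = BinaryFrame(_centered_block(N, fig_size), "target")
    mask = target.complement("metacontrast-mask")
    return target, mask


@dataclass(frozen=True)
class ScheduleEvent:
    """Presentation of one frame on one channel during [onset, onset+duration) ms.

    ``gain`` scales (and signs) the contribution: +1 for ordinary drive,
    -1 for the OFF-population negative image, 3 for a high-contrast
    target, etc.
    """

    channel: int
    frame: BinaryFrame
    onset_ms: float
    duration_ms: float
    gain: float = 1.0

    def __post_init__(self):
        if self.onset_ms < 0 or self.duration_ms < 0:
            raise ValueError("event onset and duration must be non-negative")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


class StimulusSchedule:
    """Time-resolved input fields for every channel of the network.

    The field of channel ``ch`` at Euler step ``k`` (step covers
    ``[k*dt, (k+1)*dt)`` ms) is

        sum over distinct gains g of  g * OR{ frames of ch's events with
        gain g active at step k }

    Events are active on steps whose start time lies in [onset, offset).
    Fields are cached per interval of constant active-event set, so
    repeated per-step queries are cheap.
    """

    def __init__(self, events: list[ScheduleEvent], n_channels: int | None = None):
        self.events = list(events)
        if self.events:
            ns = {ev.frame.n for ev in self.events}
            if len(ns) > 1:
                raise ValueError(f"all frames must share one grid size, got {sorted(ns)}")
            self.n = ns.pop()
        else:
            self.n = None
        self.n_channels = (
            n_channels
            if n_channels is not None
            else (max((ev.channel for ev in self.events), default=-1) + 1)
        )
        for ev in self.events:
            if not 0 <= ev.channel < self.n_channels:
                raise ValueError(f"event channel {ev.channel} out of range")
        self._cache: dict[frozenset, np.ndarray] = {}

    @property
    def end_ms(self) -> float:
        """Offset of the last event (0 for an empty schedule)."""
        return max((ev.offset_ms for ev in self.events), default=0.0)

    def active_events(self, t_ms: float) -> list[int]:
        return [
            i
            for i, ev in enumerate(self.events)
            if ev.onset_ms <= t_ms + 1e-9 and t_ms < ev.offset_ms - 1e-9
        ]

    def input_field(self, step: int, dt: float, N: int | None = None) -> np.ndarray:
        """Signed drive field per channel at one Euler step, shape (n_channels, N, N)."""
        N = N if N is not None else self.n
        if N is None:
            raise ValueError("grid size unknown for an empty schedule; pass N explicitly")
        key = frozenset(self.active_events(step * dt))
        cached = self._cache.get(key)
        if cached is not None and cached.shape[1] == N:
            return cached
        out = np.zeros((self.n_channels, N, N), dtype=float)
        by_gain: dict[tuple[int, float], np.ndarray] = {}
        for i in key:
            ev = self.events[i]
            k = (ev.channel, ev.gain)
            acc = by_gain.get(k)
            by_gain[k] = ev.frame.pixels if acc is None else np.maximum(acc, ev.frame.pixels)
        for (ch, gain), union in by_gain.items():
            out[ch] += gain * union
        self._cache[key] = out
        return out


def build_schedule(
    events: list[tuple], n_channels: int | None = None
) -> StimulusSchedule:
    """Build a schedule from (channel, frame, onset_ms, duration_ms[, gain]) tuples."""
    evs = [ScheduleEvent(*e) for e in events]
    return StimulusSchedule(evs, n_channels=n_channels)


def frame_to_pgm(frame: BinaryFrame, path) -> None:
    """Write a frame as a plain-text PGM image for quick inspection."""
    px = frame.pixels
    with open(path, "w") as fh:
        fh.write(f"P2\n{px.shape[1]} {px.shape[0]}\n1\n")
        for row in px:
            fh.write(" ".join(str(int(x)) for x in row) + "\n")
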