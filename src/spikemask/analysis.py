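"""Response metrics: region spike counts, rates, figure-ground modulation,
suppression curves and dip locations.

The figure-ground modulation index is the plain difference F - G between
the mean per-neuron spike counts at the figure and ground regions,
averaged over both feature channels, in the first 50 ms after stimulus
onset.  Masking strength is expressed as the percentage suppression
100 * (1 - masked / control) of the layer-2 central-region count in the
experiment's analysis window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import SpikeRaster
from .stimuli import _centered_block

__all__ = [
    "figure_region",
    "ground_region",
    "count_spikes",
    "firing_rate",
    "modulation_index",
    "suppression_curve",
    "find_dips",
]


def figure_region(N: int, fig_size: int = 16) -> np.ndarray:
    """Boolean mask of the centred figure block."""
    return _centered_block(N, fig_size).astype(bool)


def ground_region(N: int, fig_size: int = 16) -> np.ndarray:
    """Boolean mask of everything outside the figure block (no border buffer)."""
    return ~figure_region(N, fig_size)


def count_spikes(
    raster: SpikeRaster,
    region: np.ndarray,
    window_ms: tuple[float, float],
    layer: int,
    channels=(0, 1),
) -> float:
    """Mean per-neuron spike count of a region in [t0, t1) ms.

    Counts are averaged over the region's neurons and over the listed
    channels (both feature channels by default, matching how figure and
    ground responses are reported).
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    if np.isscalar(channels):
        channels = (channels,)
    per_ch = [
        raster.spike_counts(ch, layer, window_ms)[region].mean() for ch in channels
    ]
    return float(np.mean(per_ch))


def firing_rate(count: float, window_ms: float) -> float:
    """Convert a per-neuron spike count in a window to spikes/sec."""
    if window_ms <= 0:
        raise ValueError("window must be positive")
    return count * 1000.0 / window_ms


def modulation_index(F: float, G: float) -> float:
    """Figure-ground modulation: the raw difference F - G."""
    return F - G


def suppression_curve(responses: pd.Series | dict, control: float) -> pd.Series:
    """Percentage suppression 100*(1 - response/control) indexed like the input.

    ``control`` is the unmasked (target-only) response; it must be
    positive.  Values are <= 100; negative values mean facilitation.
    """
    if control <= 0:
        raise ValueError("control response must be positive")
    s = pd.Series(responses, dtype=float)
    return 100.0 * (1.0 - s / control)


def find_dips(values, index=None) -> list:
    """Locations of local minima of a curve, ties broken to the smaller index.

    A dip is a maximal run of equal values, interior to the curve, that
    is strictly below both neighbouring values; the first point of the
    run is reported.
    """
    v = np.asarray(pd.Series(values, dtype=float))
    idx = np.asarray(index if index is not None else
                     (values.index if isinstance(values, pd.Series) else np.arange(len(v))))
    dips = []
    i = 0
    n = len(v)
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and v[i - 1] > v[i] and v[j + 1] > v[i]:
            dips.append(idx[i])
        i = j + 1
    return dips
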