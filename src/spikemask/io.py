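"""Configuration files, result/raster serialization and run manifests.

Configs are YAML (or JSON) mappings whose keys mirror
:class:`~spikemask.experiments.ExperimentConfig`; unknown keys are
rejected with their path, and an empty file yields the full default
configuration.  Results round-trip through CSV; rasters are stored as an
HDF5 container plus a plain-text spike-event list.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiments import ExperimentConfig, ExperimentResult
from .network import SpikeRaster
from .neuron import IzhikevichParams

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "write_results",
    "read_results",
    "write_raster",
    "read_raster",
    "RunManifest",
]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


_NEURON_FIELDS = {f.name for f in dataclasses.fields(IzhikevichParams)}
_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)}


def _coerce(raw: dict) -> ExperimentConfig:
    raw = dict(raw or {})
    neuron_raw = raw.pop("params", {}) or {}
    bad = set(neuron_raw) - _NEURON_FIELDS
    if bad:
        raise ConfigError(f"unknown neuron parameter(s): params.{sorted(bad)[0]}")
    bad = set(raw) - _CONFIG_FIELDS
    if bad:
        raise ConfigError(f"unknown config field(s): {sorted(bad)[0]}")
    for key in ("fg_soas", "meta_soas", "rep_soas", "target_durations", "mask_durations"):
        if key in raw:
            raw[key] = tuple(float(x) for x in raw[key])
    if "fg_window_ms" in raw:
        raw["fg_window_ms"] = tuple(float(x) for x in raw["fg_window_ms"])
    try:
        params = IzhikevichParams(**neuron_raw)
        cfg = ExperimentConfig(params=params, **raw)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err
    if cfg.dt <= 0:
        raise ConfigError(f"dt must be positive, got {cfg.dt}")
    if not 0 <= cfg.mask_p <= 1:
        raise ConfigError(f"mask_p must lie in [0,1], got {cfg.mask_p}")
    if cfg.n_mask_seeds < 1:
        raise ConfigError("n_mask_seeds must be at least 1")
    if any(d <= 0 for d in cfg.target_durations + cfg.mask_durations):
        raise ConfigError("durations must be positive")
    if list(cfg.fg_soas) != sorted(cfg.fg_soas):
        raise ConfigError("fg_soas must be sorted ascending")
    return cfg


def load_config(path) -> ExperimentConfig:
    """Read an experiment configuration; missing fields take the defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return _coerce(raw)


def config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["params"] = dataclasses.asdict(config.params)
    return d


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def write_results(result: ExperimentResult, path) -> None:
    """Write the tidy result table as CSV (lossless for the data columns)."""
    result.data.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_raster(raster: SpikeRaster, path, events_path=None) -> None:
    """Store a raster as HDF5 (bit-packed) plus an optional CSV event list."""
    import h5py

    with h5py.File(path, "w") as fh:
        packed = np.packbits(raster.data.astype(np.uint8), axis=-1)
        ds = fh.create_dataset("spikes_packed", data=packed, compression="gzip")
        ds.attrs["dt_ms"] = raster.dt
        ds.attrs["shape"] = raster.data.shape
    if events_path is not None:
        raster.to_events().to_csv(events_path, index=False)


def read_raster(path) -> SpikeRaster:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["spikes_packed"]
        shape = tuple(int(x) for x in ds.attrs["shape"])
        data = np.unpackbits(ds[...], axis=-1, count=shape[-1]).astype(bool)
        return SpikeRaster(data.reshape(shape), float(ds.attrs["dt_ms"]))


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    experiment: str
    config: dict
    master_seed: int
    outputs: dict = dataclasses.field(default_factory=dict)
    wall_time_s: float | None = None
    version: str = ""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
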