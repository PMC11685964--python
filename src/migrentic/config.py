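"""Structured (YAML) run configuration.

A single nested mapping mirrors the dataclass layout of RunConfig:

.. code-block:: yaml

    seed: 1
    n_boot: 1000
    params:
      n_birds: 60
      colonies: [{name: Skomer, lon: -5.29, lat: 51.74}]
    geo:
      sun_elev: -4.5
    stop:
      posterior_threshold: 0.66

Unknown keys raise immediately; CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from . import enviro, geolocate, immersion, stopover, synth
from .pipeline import RunConfig

__all__ = ["load_config", "dump_config"]

_SECTIONS = {
    "params": synth.PopulationParams,
    "geo": geolocate.GeolocationConfig,
    "imm": immersion.ImmersionConfig,
    "stop": stopover.StopoverConfig,
    "chl": enviro.ChlConfig,
    "light_noise": synth.LightNoise,
}


def _build(cls, mapping):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in mapping.items():
        if cls is synth.PopulationParams and k == "colonies":
            v = tuple(synth.Colony(**c) for c in v)
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], val or {})
        else:
            scalar_fields = {
                f.name for f in dataclasses.fields(RunConfig)
            } - set(_SECTIONS)
            if key not in scalar_fields:
                raise ValueError(f"unknown config key: {key}")
            kwargs[key] = val
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path):
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return o

    blob = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(blob, default_flow_style=False))
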