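"""YAML model configuration: one file covering every tunable parameter.

The file has four sections — ``lue``, ``hydro``, ``carbon``, ``run`` —
whose keys map one-to-one onto the parameter dataclass fields.  Omitted
keys keep their defaults, so a minimal config is an empty file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .hydrology import HydroParams
from .lue_npp import LueParams
from .simulate import RunConfig
from .soil_carbon import CarbonParams

__all__ = ["ModelConfig", "load_config", "dump_config"]


@dataclass
class ModelConfig:
    lue: LueParams = field(default_factory=LueParams)
    hydro: HydroParams = field(default_factory=HydroParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    run: RunConfig = field(default_factory=RunConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

        return {name: enc(getattr(self, name)) for name in ("lue", "hydro", "carbon", "run")}

    def content_hash(self) -> str:
        """Stable digest of the full parameter set, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTIONS = {"lue": LueParams, "hydro": HydroParams, "carbon": CarbonParams, "run": RunConfig}


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for section, cls in _SECTIONS.items():
        data = dict(raw.get(section) or {})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        for key, val in data.items():
            if isinstance(val, list):
                data[key] = tuple(val)
        kwargs[section] = cls(**data)
    return ModelConfig(**kwargs)


def dump_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
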