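"""YAML configuration: flat key-value sections mirroring the simulator,
environment, training and analysis parameter tables."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .agents import TrainConfig
from .behaviour import ModuleThresholds
from .environment import EnvConfig
from .plume import PlumeConfig

__all__ = ["Config", "load_config", "save_config"]


def _build(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass
class Config:
    plume: PlumeConfig = field(default_factory=PlumeConfig)
    environment: EnvConfig = field(default_factory=EnvConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    thresholds: ModuleThresholds = field(default_factory=ModuleThresholds)

    def to_dict(self) -> dict:
        return {"plume": asdict(self.plume),
                "environment": asdict(self.environment),
                "training": asdict(self.training),
                "thresholds": asdict(self.thresholds)}


def load_config(path) -> Config:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return Config(
        plume=_build(PlumeConfig, d.get("plume", {})),
        environment=_build(EnvConfig, d.get("environment", {})),
        training=_build(TrainConfig, d.get("training", {})),
        thresholds=_build(ModuleThresholds, d.get("thresholds", {})),
    )


def save_config(cfg: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
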