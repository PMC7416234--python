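"""Pipeline configuration: one validated object covering every stage.

Defaults are the tuned operating point for this problem family: MST window
scales p = 0.85, q = 1 on the 1-35 Hz grid, and a 100-particle,
100-iteration swarm with c1 = c2 = 1.5, inertia 0.8 -> 0.4 and velocity
bound 20.  Config files (YAML or JSON) may override any subset of fields;
unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pso import PSOConfig
from .stockwell import MSTConfig

__all__ = ["PipelineConfig"]

_SCHEMES = ("feature", "channel", "channel-feature", "none")


@dataclass
class PipelineConfig:
    mst: MSTConfig = field(default_factory=MSTConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    pso_feature: PSOConfig | None = None  # channel-feature phase 2; defaults to `pso`
    scheme: str = "feature"
    max_level: int = 10
    max_level_feature: int | None = None
    target_fs: float = 100.0
    val_fraction: float = 0.25
    test_fraction: float = 0.25
    standardize: bool = True
    target_coding: str = "label"
    use_scores: bool = False
    fitness_on_eval: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")
        if self.max_level < 1:
            raise ValueError("max_level must be at least 1")
        if self.max_level_feature is not None and self.max_level_feature < 1:
            raise ValueError("max_level_feature must be at least 1")
        if not 0 < self.val_fraction < 1 or not 0 < self.test_fraction < 1:
            raise ValueError("val_fraction and test_fraction must lie in (0, 1)")
        if self.target_fs <= 0:
            raise ValueError("target_fs must be positive")
        if self.target_coding not in ("label", "balanced"):
            raise ValueError("target_coding must be 'label' or 'balanced'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for sub_name, sub_cls in (("mst", MSTConfig), ("pso", PSOConfig), ("pso_feature", PSOConfig)):
            if sub_name in d:
                sub = d.pop(sub_name)
                if sub is None:
                    kwargs[sub_name] = None
                    continue
                allowed = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(sub) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in '{sub_name}' section: {sorted(unknown)}")
                kwargs[sub_name] = sub_cls(**sub)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
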