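"""Configuration file support.

A single YAML (or JSON) file with sections mirroring the pipeline
stages; every key has the library default, so a partial file is fine.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .environment import EnvConfig
from .rewards import RewardConfig
from .training import PPOConfig


@dataclass
class PreprocessingConfig:
    n_segments: int = 300
    compactness: float = 10.0
    canny_low: float = 0.1
    canny_high: float = 0.2
    polarity: str = "dark"


@dataclass
class OffsetsConfig:
    n_levels: int = 3
    spacing: float = 6.0


@dataclass
class PipelineConfig:
    n_agents: int = 16
    step_cap_factor: float = 4.0    # cap = factor * boundary / step


@dataclass
class CurriculumConfig:
    window: int = 20
    rel_tol: float = 0.02


@dataclass
class MadsegConfig:
    preprocessing: PreprocessingConfig = field(
        default_factory=PreprocessingConfig)
    offsets: OffsetsConfig = field(default_factory=OffsetsConfig)
    env: EnvConfig = field(default_factory=EnvConfig)
    rewards: RewardConfig = field(default_factory=RewardConfig)
    ppo: PPOConfig = field(default_factory=PPOConfig)
    curriculum: CurriculumConfig = field(default_factory=CurriculumConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "MadsegConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            section = data.get(f.name, {})
            factory = f.default_factory
            if section:
                kwargs[f.name] = factory(**section)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        import yaml

        data = {f.name: dataclasses.asdict(getattr(self, f.name))
                for f in dataclasses.fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
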