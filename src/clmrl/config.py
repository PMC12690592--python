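"""Run configuration: a flat, schema-validated document plus named presets.

Every hyperparameter of the training loop lives here. Unknown keys are
rejected so a typo in a YAML file fails loudly instead of silently running
the default. Presets mirror well-known algorithm families; the combined
"acegen" presets are representative configurations of this toolkit, with
every value exposed in the shipped schema.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PolicyConfig(_Strict):
    embedding_size: int = Field(64, ge=1)
    hidden_size: int = Field(128, ge=1)
    max_len: int = Field(100, ge=2)


class RewardConfig(_Strict):
    name: str = "motif"
    params: dict = Field(default_factory=dict)


class BaselineConfig(_Strict):
    kind: Literal["none", "mab", "loo"] = "none"
    beta: float = Field(0.1, gt=0.0, le=1.0)


class HillClimbConfig(_Strict):
    k_ratio: float = Field(1.0, gt=0.0, le=1.0)


class ReplayConfig(_Strict):
    enabled: bool = False
    capacity: int = Field(100, ge=1)
    batch_size: int = Field(20, ge=1)
    mode: Literal["prioritized", "uniform"] = "prioritized"


class ShapingSection(_Strict):
    formulation: Literal["none", "reinvent", "proposed"] = "none"
    sigma: float = Field(0.0, ge=0.0)
    alpha: float = Field(1.0, ge=1.0)
    per_token_prior: bool = False


class RegularizationConfig(_Strict):
    lambda_kl: float = Field(0.0, ge=0.0)
    lambda_ent: float = Field(0.0, ge=0.0)
    lambda_all: float = Field(0.0, ge=0.0)


class DiversityConfig(_Strict):
    mode: Literal["off", "occurrence", "bin"] = "off"
    bin_threshold: int = Field(25, ge=1)


class RNDConfig(_Strict):
    lambda_rnd: float = Field(0.0, ge=0.0)
    learning_rate: float = Field(1e-3, gt=0.0)
    n_features: int = Field(1024, ge=8)


class ScheduleConfig(_Strict):
    kind: Literal["constant", "cosine"] = "constant"
    base_rate: float = Field(1e-4, gt=0.0)
    anneal_start: float = Field(5e-4, gt=0.0)
    anneal_end: float = Field(1e-4, gt=0.0)
    anneal_fraction: float = Field(0.5, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.anneal_end > self.anneal_start:
            raise ValueError("anneal_end must be <= anneal_start")
        return self


class PretrainConfig(_Strict):
    corpus_path: Optional[str] = None     # .smi file; None -> generated toy corpus
    corpus_seed: int = 123
    corpus_size: int = Field(1000, ge=1)
    epochs: int = Field(30, ge=0)
    batch_size: int = Field(64, ge=1)
    learning_rate: float = Field(2e-3, gt=0.0)


class RunConfig(_Strict):
    seed: int = 0
    budget: int = Field(10000, ge=1)
    batch_size: int = Field(64, ge=1)
    policy: PolicyConfig = Field(default_factory=PolicyConfig)
    reward: RewardConfig = Field(default_factory=RewardConfig)
    baseline: BaselineConfig = Field(default_factory=BaselineConfig)
    hill_climb: HillClimbConfig = Field(default_factory=HillClimbConfig)
    replay: ReplayConfig = Field(default_factory=ReplayConfig)
    shaping: ShapingSection = Field(default_factory=ShapingSection)
    regularization: RegularizationConfig = Field(default_factory=RegularizationConfig)
    diversity: DiversityConfig = Field(default_factory=DiversityConfig)
    rnd: RNDConfig = Field(default_factory=RNDConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    pretrain: PretrainConfig = Field(default_factory=PretrainConfig)
    prior_checkpoint: Optional[str] = None
    output_dir: Optional[str] = None
    zero_invalid: bool = True             # invalid molecules score 0 before shaping

    @model_validator(mode="after")
    def _budget_covers_batch(self):
        if self.budget < self.batch_size:
            raise ValueError("budget must be >= batch_size")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as handle:
            data = yaml.safe_load(handle) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def override(self, dotted: dict) -> "RunConfig":
        """New config with dotted-path overrides, e.g. {'hill_climb.k_ratio': 0.5}."""
        data = self.model_dump()
        for path, value in dotted.items():
            node = data
            *parents, leaf = path.split(".")
            for part in parents:
                node = node[part]
            if leaf not in node:
                raise KeyError(f"unknown config key {path!r}")
            node[leaf] = value
        return RunConfig.model_validate(data)


def presets() -> dict[str, RunConfig]:
    """Named configurations mirroring the usual algorithm families."""
    base = RunConfig()
    table = {
        "plain-reinforce": {},
        "reinvent-style": {
            "shaping.formulation": "reinvent",
            "shaping.sigma": 60.0,
            "replay.enabled": True,
            "replay.capacity": 100,
            "replay.batch_size": 10,
            "replay.mode": "prioritized",
            "regularization.lambda_all": 1.0,
        },
        "ahc-style": {
            "shaping.formulation": "reinvent",
            "shaping.sigma": 60.0,
            "hill_climb.k_ratio": 0.5,
        },
        "acegen-practical": {
            "shaping.formulation": "proposed",
            "shaping.sigma": 0.002,
            "shaping.alpha": 3.0,
            "baseline.kind": "mab",
            "hill_climb.k_ratio": 0.5,
            "replay.enabled": True,
            "replay.capacity": 100,
            "replay.batch_size": 10,
            "replay.mode": "uniform",
            "regularization.lambda_kl": 0.1,
        },
        "acegen-molopt": {
            "shaping.formulation": "proposed",
            "shaping.sigma": 0.001,
            "shaping.alpha": 5.0,
            "baseline.kind": "mab",
            "hill_climb.k_ratio": 0.25,
            "replay.enabled": True,
            "replay.capacity": 100,
            "replay.batch_size": 20,
            "replay.mode": "prioritized",
            "schedule.kind": "cosine",
            "schedule.anneal_start": 5e-4,
            "schedule.anneal_end": 1e-4,
        },
    }
    return {name: base.override(overrides) for name, overrides in table.items()}


def get_preset(name: str) -> RunConfig:
    available = presets()
    if name not in available:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(available)}")
    return available[name]


DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "hill_climb.k_ratio": [1.0, 0.75, 0.5, 0.25],
    "baseline.kind": ["none", "mab", "loo"],
    "shaping.alpha": [1.0, 2.0, 3.0, 4.0, 5.0],
    "shaping.sigma": [0.0, 0.001, 0.005],
    "replay.enabled": [False, True],
    "replay.capacity": [100, 500],
    "replay.batch_size": [10, 20],
    "replay.mode": ["prioritized", "uniform"],
    "regularization.lambda_kl": [0.0, 0.01, 0.1],
    "schedule.base_rate": [1e-4, 5e-4, 1e-3],
}
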