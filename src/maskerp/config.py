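"""Run configuration: a schema-checked, YAML-serializable bundle of every
stage's parameters, all seeded from one master seed."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StimuliConfig(_Strict):
    n_exemplars: int = 8
    size: int = 128
    block_px: int = 10
    generate: bool = False  # image synthesis is optional in a full run


class DesignConfig(_Strict):
    n_versions: int = 4
    max_run: int = 3
    max_attempts: int = 10_000


class CohortConfig(_Strict):
    n_participants: int = 8
    scale: str = "reduced"  # reduced: 480 trials/participant; full: 960
    outlier_participants: list[int] = Field(default_factory=list)


class ErpConfig(_Strict):
    apply_filter: bool = True
    filter_low_hz: float = 0.01
    filter_high_hz: float = 40.0
    abs_max_uv: float = 120.0
    gradient_max_uv: float = 75.0
    low_signal_min_uv: float = 0.01
    min_trials: int = 20
    bad_channels: list[str] = Field(default_factory=list)


class StatsConfig(_Strict):
    q: float = 0.05
    prior_scale: float = 0.7071067811865476
    min_n: int = 40
    bf_upper: float = 3.0
    bf_lower: float = 0.3333333333333333


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "maskerp_out"
    stimuli: StimuliConfig = Field(default_factory=StimuliConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    erp: ErpConfig = Field(default_factory=ErpConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
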