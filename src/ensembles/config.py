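"""Run configuration: validated, hashable, serializable round-trip."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field

from .bayes import SEQUENTIAL_BF_HIGH, SEQUENTIAL_BF_LOW, SEQUENTIAL_N_START
from .observers import CohortParams
from .screening import CHANCE_LEVEL, FIT_THRESHOLD


class DesignConfig(BaseModel):
    n_versions: int = Field(default=5, ge=1)
    version: int = Field(default=1, ge=1)
    sd_tolerance: float = Field(default=0.5, gt=0)
    max_restarts: int = Field(default=10_000, ge=1)


class ScreeningConfig(BaseModel):
    chance_level: float = Field(default=CHANCE_LEVEL, ge=0, le=1)
    fit_threshold: float = FIT_THRESHOLD
    manual_exclude: list[int] = Field(default_factory=list)


class PriorConfig(BaseModel):
    kappa: float = Field(default=1.0, gt=0)


class SequentialConfig(BaseModel):
    enabled: bool = True
    n_start: int = Field(default=SEQUENTIAL_N_START, ge=4)
    threshold_high: float = Field(default=SEQUENTIAL_BF_HIGH, gt=1)
    threshold_low: float = Field(default=SEQUENTIAL_BF_LOW, gt=0, lt=1)
    batch: int = Field(default=1, ge=1)


class RunConfig(BaseModel):
    seed: int = 0
    design: DesignConfig = Field(default_factory=DesignConfig)
    cohort: CohortParams = Field(default_factory=CohortParams)
    screening: ScreeningConfig = Field(default_factory=ScreeningConfig)
    prior: PriorConfig = Field(default_factory=PriorConfig)
    sequential: SequentialConfig = Field(default_factory=SequentialConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate_json(text)
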