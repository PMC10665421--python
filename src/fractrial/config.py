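"""Pipeline configuration: one validated, serializable object per run.

The config file is YAML with one section per stage (``population``,
``loads``, ``geometry``, ``materials``) plus top-level run settings.  An
empty file yields the full default configuration.  Unknown keys are
rejected with field-level messages.

The per-avatar tibia length overrides ``geometry.tibia_length`` during the
run; the value in the config only serves as the standalone default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .gait_loads import GaitLoadConfig
from .population import PopulationConfig
from .surrogate_mechanics import Materials, SurrogateGeometry

__all__ = ["PipelineConfig", "read_config"]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_avatars: int = 300
    export_strain_field: bool = False
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    loads: GaitLoadConfig = Field(default_factory=GaitLoadConfig)
    geometry: SurrogateGeometry = Field(default_factory=SurrogateGeometry)
    materials: Materials = Field(default_factory=Materials)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def read_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a pipeline config; ``None`` gives pure defaults.

    Keyword overrides (e.g. ``seed=7``, ``n_avatars=50``) are applied on top
    of the file contents.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping at top level")
            data = loaded
    data.update(overrides)
    return PipelineConfig.model_validate(data)
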