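"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    extent: tuple[float, float, float, float] = (-180.0, 180.0, 50.0, 90.0)
    cell_size_deg: float = Field(2.0, gt=0)
    n_regions: int = Field(8, ge=1)

    @model_validator(mode="after")
    def _lat_span(self):
        if self.extent[3] - self.extent[2] < 10:
            raise ValueError("extent must span >= 10 degrees latitude")
        return self


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    year_start: int = 2000
    n_years: int = Field(20, ge=2)
    n_apex: int = Field(4, ge=1)
    n_meso: int = Field(8, ge=1)
    n_samples_per_year: int = Field(80, ge=1)

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_start + self.n_years))


class PrepConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    thin_km: float = Field(100.0, gt=0)
    thin_reps: int = Field(10, ge=1)
    pseudoabsence_per_year: int = Field(500, ge=1)
    buffer_km: float = Field(100.0, ge=0)


class SDMConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    algorithms: list[str] = ["glm", "gam", "rf", "gbm", "knn"]
    candidate_variables: list[str] = [
        "SSST", "SSIC", "SCHL", "SZOOC", "salinity", "depth", "dist_coast", "dist_ice_edge",
    ]
    tss_gate: float = Field(0.7, ge=-1, le=1)
    n_splits: int = Field(3, ge=1)
    importance_permutations: int = Field(3, ge=1)


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(0.05, gt=0, lt=1)
    min_expected: float = Field(1.0, ge=0)
    accrual_min_per_decade: float = Field(1.0, gt=0)
    summer_months: list[int] = [6, 7, 8, 9]
    hotspot_bounds: dict[str, tuple[float, float]] = {}
    hotspot_p_threshold: float = Field(0.05, gt=0, lt=1)
    climatology_years: int = Field(10, ge=2)

    @field_validator("summer_months")
    @classmethod
    def _months(cls, v):
        if any(m < 1 or m > 12 for m in v):
            raise ValueError("summer months must be in 1..12")
        return v


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    output_dir: str = "runs/default"
    seed: int = 0
    grid: GridConfig = GridConfig()
    scenario: ScenarioConfig = ScenarioConfig()
    prep: PrepConfig = PrepConfig()
    sdm: SDMConfig = SDMConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode("utf8")
        return hashlib.sha256(blob).hexdigest()


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
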