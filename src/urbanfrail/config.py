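"""Declarative pipeline configuration (YAML/JSON), schema-validated.

Unknown keys are rejected; every omitted field falls back to the calibrated
defaults, so an empty config reproduces the default study scenario. Seeds
are mandatory — there is no silent entropy.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .facilities import FacilityType
from .grid import GridSpec
from .scoring import ConutBands, ScoringConfig
from .simulate import CityConfig, CohortConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Strict):
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 50.0
    n_rows: int = 100
    n_cols: int = 100

    def build(self) -> GridSpec:
        return GridSpec(**self.model_dump())


class CitySection(_Strict):
    grid: GridSection = Field(default_factory=GridSection)
    intensities: Optional[dict[str, float]] = None
    cluster_weights: Optional[tuple[float, ...]] = None

    def build(self) -> CityConfig:
        kw = {"grid": self.grid.build()}
        if self.intensities is not None:
            kw["intensities"] = {FacilityType(k): v for k, v in self.intensities.items()}
        if self.cluster_weights is not None:
            kw["cluster_weights"] = self.cluster_weights
        return CityConfig(**kw)


class CohortSection(_Strict):
    n_participants: int = 251
    n_lab_subset: int = 70
    target_frailty_prevalence: float = 0.175
    frailty_index_slope: float = 0.4

    def build(self) -> CohortConfig:
        return CohortConfig(**self.model_dump())


class ScoringSection(_Strict):
    frailty_threshold: float = 25.0
    fts3_subset: tuple[str, str, str] = ("physical_activity", "strength", "gait_speed")
    albumin_bounds: tuple[float, float, float] = (3.50, 3.00, 2.50)
    lymphocyte_bounds: tuple[float, float, float] = (1600, 1200, 800)
    cholesterol_bounds: tuple[float, float, float] = (180, 140, 100)

    def build(self) -> ScoringConfig:
        return ScoringConfig(
            frailty_threshold=self.frailty_threshold,
            fts3_subset=self.fts3_subset,
            conut_bands=ConutBands(
                albumin_bounds=self.albumin_bounds,
                lymphocyte_bounds=self.lymphocyte_bounds,
                cholesterol_bounds=self.cholesterol_bounds,
            ),
        )


class StatsSection(_Strict):
    test_method: str = "auto"
    ci_method: str = "wilson"
    alpha: float = 0.05

    @field_validator("test_method")
    @classmethod
    def _check_method(cls, v: str) -> str:
        if v not in ("auto", "t", "mann_whitney"):
            raise ValueError(f"unknown test method {v!r}")
        return v


class PipelineConfig(_Strict):
    seed: int
    city: CitySection = Field(default_factory=CitySection)
    cohort: CohortSection = Field(default_factory=CohortSection)
    scoring: ScoringSection = Field(default_factory=ScoringSection)
    stats: StatsSection = Field(default_factory=StatsSection)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    @classmethod
    def default(cls, seed: int) -> "PipelineConfig":
        return cls(seed=seed)
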