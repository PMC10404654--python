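"""Run configuration: a versioned, schema-checked YAML block.

Unknown keys are rejected so typos fail loudly; every stochastic stage
derives its seed from the master seed plus the stage name, making a full run
a pure function of its config.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthConfig(_Block):
    n_rows: int = 200
    n_cols: int = 200
    cell_size_km: float = Field(1.0, gt=0)
    n_climate_layers: int = Field(5, ge=4)
    autocorrelation_range_cells: float = Field(15.0, gt=0)
    landcover_classes: int = Field(5, ge=3)
    river_count: int = Field(3, ge=0)
    road_count: int = Field(4, ge=0)
    n_occurrences: int = Field(600, ge=1)
    active_predictors: list[str] = ["bio18", "elevation", "human_footprint"]
    coefficients: list[float] = [4.0, -4.0, -2.5]
    intercept: float = -4.0
    pa_count: int = Field(6, ge=0)
    zone_count: int = Field(4, ge=1)


class ScenarioConfig(_Block):
    offsets: dict[str, float] = {}
    scales: dict[str, float] = {}
    landcover_conversion: float = Field(0.0, ge=0.0, le=1.0)


class ThinningConfig(_Block):
    min_dist_km: float = Field(5.0, gt=0)
    n_restarts: int = Field(100, ge=1)
    method: str = "distance"

    @field_validator("method")
    @classmethod
    def _method(cls, v):
        if v not in ("distance", "grid"):
            raise ValueError("thinning.method must be 'distance' or 'grid'")
        return v


class VifConfig(_Block):
    threshold: float = Field(10.0, gt=1.0)
    subsample: int = Field(10_000, ge=100)


class ModelConfig(_Block):
    families: list[str] = ["GLM", "MARS", "BRT", "RF", "MAXENT"]
    n_replicates: int = Field(10, ge=1)
    n_folds: int = Field(5, ge=2)
    train_fraction: float = Field(0.7, gt=0.0, lt=1.0)
    inclusion_auc: float = Field(0.8, ge=0.0, le=1.0)
    weight_metric: str = "TSS"
    exclusion_km: float = Field(5.0, ge=0.0)
    n_background: int = Field(10_000, ge=100)
    learner_params: dict[str, dict] = {}
    project_future: list[str] = ["LCAm", "Cm"]

    @field_validator("project_future")
    @classmethod
    def _no_habitat_future(cls, v):
        if "HLCAm" in v:
            raise ValueError(
                "HLCAm cannot be projected to future scenarios: its habitat layers "
                "(NDVI, forest type, tree canopy) have no future analogue, so only "
                "LCAm and Cm are projected"
            )
        return v


class NullModelConfig(_Block):
    enabled: bool = True
    n_iter: int = Field(99, ge=19)
    families: list[str] = ["GLM"]
    n_replicates: int = Field(2, ge=1)


class EvaluationConfig(_Block):
    boyce_bins: int = Field(101, ge=10)
    null_model: NullModelConfig = NullModelConfig()


class ClassificationConfig(_Block):
    bounds: list[float] = [0.2, 0.4, 0.6]

    @field_validator("bounds")
    @classmethod
    def _bounds(cls, v):
        if len(v) != 3 or not all(0 < b < 1 for b in v) or sorted(v) != v:
            raise ValueError("classification.bounds must be three increasing values in (0,1)")
        return v


class PriorityConfig(_Block):
    disturbance_threshold: float = Field(0.3, gt=0.0, lt=1.0)
    require_all_scenarios: bool = True


class ThreatConfig(_Block):
    esz_width_km: float = Field(1.0, gt=0)
    disturbance_threshold: float = Field(0.3, gt=0.0, lt=1.0)
    road_km: float = Field(3.0, ge=0.0)
    flag_threshold: float = Field(0.3, gt=0.0, lt=1.0)


class RunConfig(_Block):
    """Top-level pipeline configuration (all blocks optional, all defaulted)."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    seed: int = 0
    synth: SynthConfig = SynthConfig()
    scenarios: dict[str, ScenarioConfig] = {
        "rcp45": ScenarioConfig(offsets={"bio18": 12.0, "bio19": 8.0}, landcover_conversion=0.05),
        "rcp85": ScenarioConfig(offsets={"bio18": 30.0, "bio19": 20.0}, landcover_conversion=0.10),
    }
    thinning: ThinningConfig = ThinningConfig()
    variable_sets: dict[str, list[str]] = {}
    vif: VifConfig = VifConfig()
    model: ModelConfig = ModelConfig()
    evaluation: EvaluationConfig = EvaluationConfig()
    classification: ClassificationConfig = ClassificationConfig()
    priority: PriorityConfig = PriorityConfig()
    threat: ThreatConfig = ThreatConfig()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: crc32 of the stage name mixed with
        the master seed, kept below 2**31."""
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def validate_config(path_or_dict) -> RunConfig:
    """Load + schema-check a YAML config; errors name the offending key.

    A missing ``seed`` defaults to 0 with a warning.
    """
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    if "seed" not in raw:
        logger.warning("config has no 'seed'; defaulting to 0")
    return RunConfig(**raw)
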