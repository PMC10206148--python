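"""Pipeline configuration: schema-validated, unknown keys rejected."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SurveySection(_Section):
    n_images: int = Field(20, ge=1)
    image_width: int = Field(256, ge=64)
    image_height: int = Field(256, ge=64)
    nodule_density: float = Field(40.0, ge=0)
    fauna_rate: float = Field(2.0, ge=0)
    laser_rate: float = Field(0.5, ge=0)
    dark_patch_rate: float = Field(0.3, ge=0)
    noise_sigma: float = Field(0.02, ge=0, le=1)
    start_lon: float = -125.0
    start_lat: float = 11.8
    heading_deg: float = 90.0
    speed_ms: float = 0.26
    interval_s: float = Field(10.0, gt=0)


class SegmentationSection(_Section):
    scale: float = Field(100.0, gt=0)
    sigma: float = Field(1.0, ge=0)
    min_size: int = Field(50, ge=1)
    max_area_fraction: float = Field(0.25, gt=0, le=1)
    patch_size: int = Field(32, ge=8)
    n_sample_images: int = Field(50, ge=1)  # subsample for training the models


class VaeSection(_Section):
    latent_dim: int = Field(100, ge=2)
    hidden_dim: int = Field(128, ge=4)
    epochs: int = Field(16, ge=1)
    batch_size: int = Field(64, ge=1)
    learning_rate: float = Field(1e-3, gt=0)


class IforestSection(_Section):
    n_trees: int = Field(100, ge=1)
    subsample_size: int = Field(256, ge=2)
    contamination: float = Field(0.4, gt=0, le=0.5)


class FilterSection(_Section):
    method: str = Field("classifier", pattern="^(classifier|threshold)$")
    percentile: float = Field(75.0, gt=0, lt=100)
    prob_cutoff: float = Field(0.5, ge=0, le=1)
    classifier_epochs: int = Field(300, ge=1)
    classifier_lr: float = Field(1e-3, gt=0)


class EvaluationSection(_Section):
    miss_rate: float = Field(0.0, ge=0, le=1)
    fp_rate: float = Field(0.0, ge=0)
    jitter_px: float = Field(0.0, ge=0)
    nms_iou: float = Field(0.5, gt=0, lt=1)


class EcologySection(_Section):
    cell_size_m: float = Field(200.0, gt=0)
    fov_x_deg: float = Field(64.0, gt=0, lt=180)
    fov_y_deg: float = Field(64.0, gt=0, lt=180)
    max_gap_s: float = Field(60.0, gt=0)


class PipelineConfig(_Section):
    """Nested configuration for every pipeline stage plus global seed/paths."""

    seed: int = 0
    workdir: str = "benthofind_run"
    survey: SurveySection = Field(default_factory=SurveySection)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    vae: VaeSection = Field(default_factory=VaeSection)
    iforest: IforestSection = Field(default_factory=IforestSection)
    filtering: FilterSection = Field(default_factory=FilterSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    ecology: EcologySection = Field(default_factory=EcologySection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(data)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed and the stage name."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)
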