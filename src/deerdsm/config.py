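"""Pipeline configuration: the survey-analysis constants in one place.

Defaults are the constants of the field protocol this pipeline mirrors:
1.5-m truncation (≈ farthest 5% of distances discarded), observer groups of
at least 70 detections, 500-m home-range buffers, |r| > 0.7 collinearity
screening, p < 0.05 backward selection, the 5%-of-data-nearby discard rule
and the 50% valid-area district filter.  Loaded from YAML with schema
validation; every run echoes the resolved configuration into its log.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class PipelineConfig(BaseModel):
    # survey / stage-1 constants
    truncation_m: float = Field(1.5, gt=0)
    min_group_detections: int = Field(70, gt=0)
    candidate_keys: tuple[str, ...] = ("half_normal", "hazard_rate")
    candidate_adjustments: tuple[str, ...] = ("cosine",)
    detection_covariates: tuple[str, ...] = ("observer_group",)
    cvm_bootstrap: int = Field(99, ge=0)
    # stage-2 constants
    buffer_radius_m: float = Field(500.0, gt=0)
    r_threshold: float = Field(0.7, gt=0, le=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    basis_df: int = Field(10, ge=4)
    # prediction / evaluation
    grid_cell_km: float = Field(1.0, gt=0)
    nearby_threshold_pct: float = Field(5.0, ge=0, le=100)
    min_valid_fraction: float = Field(0.5, ge=0, le=1)
    strict_discard: bool = True
    # synthetic world
    landscape_km: float = Field(20.0, gt=0)
    resolution_m: float = Field(100.0, gt=0)
    n_designed_transects: int = Field(120, gt=0)
    n_plot_quadrants: int = Field(25, ge=0)
    woodland_effort: float = Field(0.75, ge=0, le=1)
    n_districts: int = Field(40, gt=0)
    true_sigma_m: float = Field(0.6, gt=0)
    true_key: str = "half_normal"
    n_observers: int = Field(6, gt=0)
    # bookkeeping
    season: str = "spring"
    seed: int = Field(1, ge=0)
    outdir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
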