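"""Run configuration: one serializable object fully determines a run."""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ParameterError


class PipelineConfig(BaseModel):
    """Everything the pipeline needs beyond the movie itself.

    The JSON form of this object, together with the input movie, fully
    reproduces a run; its hash is stamped onto every output row.
    """

    model_config = ConfigDict(frozen=True)

    fluorescence_channel: str = "fluorescence"
    dic_channel: str = "dic"
    frame_interval_s: float | None = None  # None: take from movie metadata
    focus_metric: str = "laplacian_variance"
    measure_on: str = "best_focus"  # or "projection"
    # embryo mask
    local_std_radius: int = Field(2, ge=1)
    smooth_sigma: float = Field(4.0, ge=0)
    min_embryo_fraction: float = Field(0.05, gt=0, lt=1)
    # cell split
    solidity_threshold: float = Field(0.92, gt=0, le=1)
    min_cell_fraction: float = Field(0.2, gt=0, lt=0.5)
    # nuclei
    dog_sigma_small: float = Field(2.0, gt=0)
    dog_sigma_large: float = Field(8.0, gt=0)
    expected_nucleus_radius_px: float = Field(10.0, gt=0)
    # quantification
    ratio_uses_nuclear: bool = True
    # NEB
    neb_persistence: int = Field(2, ge=1)
    neb_contrast_min: float = 0.0
    # provenance
    fusion_frame: int = Field(0, ge=0)
    seed: int = 0

    @field_validator("measure_on")
    @classmethod
    def _measure_on(cls, v: str) -> str:
        if v not in ("best_focus", "projection"):
            raise ParameterError("measure_on must be 'best_focus' or 'projection'")
        return v

    @field_validator("focus_metric")
    @classmethod
    def _metric(cls, v: str) -> str:
        if v != "laplacian_variance":
            raise ParameterError("only the 'laplacian_variance' focus metric is built in")
        return v

    def model_post_init(self, __context) -> None:
        if self.dog_sigma_small >= self.dog_sigma_large:
            raise ParameterError("dog_sigma_small must be < dog_sigma_large")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
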