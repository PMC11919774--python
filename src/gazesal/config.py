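"""Run configuration: one schema-validated YAML drives the whole pipeline.

Every numeric choice the analysis depends on but the study protocol does
not fix (detector thresholds, filter order, generator noise levels) lives
here with a documented default; a serialized copy is written into each
output directory so a run is reproducible from its artifacts alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .geometry import ScreenGeometry
from .synthetic_data import (
    DEFAULT_D_OFFSETS,
    CohortDesign,
    GroupCell,
    TrialParams,
)


class GeometryConfig(BaseModel):
    width_px: int = 1280
    height_px: int = 1024
    diagonal_inch: float = 19.0
    distance_cm: float = 70.0

    def build(self) -> ScreenGeometry:
        return ScreenGeometry(self.width_px, self.height_px,
                              self.diagonal_inch, self.distance_cm)


class CohortCell(BaseModel):
    site: str
    diagnosis: str
    n: int = Field(ge=0)
    age_mean: float = 35.0
    age_sd: float = 12.0
    p_male: float = Field(default=0.5, ge=0, le=1)


class GeneratorConfig(BaseModel):
    images_per_category: int = 4
    base_pi: float = Field(default=0.30, ge=0, le=1)
    sigma_pi: float = Field(default=0.05, gt=0)
    d_offsets: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_D_OFFSETS))
    site_pi_spread: float = 0.02
    n_saccades: int = 20
    n_micro: int = 2
    jitter_sd: float = 0.05
    blink_rate: float = 1.0
    save_traces: bool = False
    #: demo cohort; scale up (or load the packaged reference structure via
    #: the library) for full-size runs
    cohort: list[CohortCell] = Field(default_factory=lambda: [
        CohortCell(site="S1", diagnosis="HC", n=8),
        CohortCell(site="S1", diagnosis="SZ", n=8),
    ])

    def design(self) -> CohortDesign:
        cells = [GroupCell(c.site, c.diagnosis, c.n, c.age_mean, c.age_sd, c.p_male)
                 for c in self.cohort]
        return CohortDesign(cells, base_pi=self.base_pi, sigma_pi=self.sigma_pi,
                            d_offsets=dict(self.d_offsets),
                            site_pi_spread=self.site_pi_spread,
                            n_saccades=self.n_saccades)

    def trial_params(self) -> TrialParams:
        return TrialParams(n_saccades=self.n_saccades, n_micro=self.n_micro,
                           jitter_sd=self.jitter_sd, blink_rate=self.blink_rate)


class DetectionConfig(BaseModel):
    f3db_hz: float = 30.0
    numtaps: int = 51
    v_onset: float = 30.0
    v_offset: float = 10.0
    min_saccade_ms: int = 8
    min_fixation_ms: int = 50
    blink_pad_ms: int = 25
    central_difference: bool = True

    def build(self):
        from .gaze_events import DetectionParams

        return DetectionParams(**self.model_dump())


class StatsConfig(BaseModel):
    ref_age: float = 35.75
    meta_groups: tuple[str, str] = ("HC", "SZ")
    include_micro: bool = False


class RunConfig(BaseModel):
    """Top-level pipeline configuration.

    ``geometry`` is required (a run is meaningless without the display
    metadata); everything else has documented defaults.
    """

    seed: int = 0
    geometry: GeometryConfig
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")
        return v

    @classmethod
    def default(cls) -> "RunConfig":
        return cls(geometry=GeometryConfig())

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False)
        )
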