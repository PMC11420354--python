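"""Pipeline configuration: every tunable default in one serializable place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .io import config_hash

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Defaults for the whole kymograph-velocimetry pipeline.

    Values are validated against the documented ranges on construction; all
    fields serialize to YAML and hash canonically (see
    :func:`glidekymo.io.config_hash`) so runs are reproducible.
    """

    # tracking
    spot_diameter_um: float = 6.0  # chloroplast bounding-circle diameter, 4-8 um
    max_gap_frames: int = 5
    smoothing_window: int = 20  # samples in the velocity moving average
    # calibration defaults (TIRF at 1x tube lens)
    pixel_size_um: float = 0.13
    frame_interval_s: float = 0.1
    # velocimetry
    roi_min_s: float = 5.0
    roi_max_s: float = 15.0
    gliding_v_min_um_s: float = 0.5
    gliding_t_min_s: float = 5.0
    histogram_bins: int = 90
    fit_r2_threshold: float = 0.5
    # kymograph
    stripe_mask_width_px: int = 2
    # population assay
    trace_min_duration_s: float = 30.0
    trace_min_distance_um: float = 50.0
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4.0 <= self.spot_diameter_um <= 8.0:
            raise ValueError("spot_diameter_um must be within 4-8 um")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration must be positive")
        if not 0 < self.roi_min_s <= self.roi_max_s:
            raise ValueError("ROI duration bounds must satisfy 0 < min <= max")
        if self.stripe_mask_width_px < 1:
            raise ValueError("stripe_mask_width_px must be >= 1")
        if self.histogram_bins < 4:
            raise ValueError("histogram_bins must be >= 4")

    @property
    def hash(self) -> str:
        return config_hash(self)


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig(**payload)
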