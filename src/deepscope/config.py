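"""Run configuration for all pipelines.

Every tunable parameter lives in one validated, JSON-serializable object so
a run can be reproduced from its config file alone.  Unknown keys are
rejected; all numeric parameters are range-checked.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CalibrationConfig(_Strict):
    """Physical calibration used when the image file carries none.

    Operations that need a calibrated quantity fail loudly if the relevant
    field is absent rather than silently assuming 1.0.
    """

    pixel_size_xy: Optional[float] = Field(default=None, gt=0, description="µm per pixel")
    z_step: Optional[float] = Field(default=None, gt=0, description="µm between z planes")
    frame_interval: Optional[float] = Field(default=None, gt=0, description="s between timepoints")


class MotilityConfig(_Strict):
    """Parameters of the microglial fine-process motility pipeline."""

    median_kernel: int = Field(default=3, ge=1)
    clahe_clip_limit: float = Field(default=0.01, gt=0)
    clahe_tiles: Tuple[int, int] = (8, 8)
    otsu_bins: int = Field(default=256, ge=2)
    min_blob_px: int = Field(default=100, ge=1)
    connectivity: Literal[4, 8] = 8
    snr_floor: float = Field(default=4.0, ge=0)
    register_frames: bool = True
    reference: Literal["first", "previous"] = "first"
    upsample: int = Field(default=10, ge=1)
    max_shift: float = Field(default=20.0, gt=0)
    pooled: bool = False
    channel: int = Field(default=0, ge=0)


class AstroConfig(_Strict):
    """Astrocyte microdomain event-detection parameters (rates in Hz/seconds)."""

    downsample: int = Field(default=3, ge=1)
    smooth_sigma_s: float = Field(default=1.0, ge=0)
    threshold_z: float = 3.0
    min_sep_s: float = Field(default=1.0, ge=0)
    baseline_window_s: float = Field(default=10.0, gt=0)
    roi_min_area: int = Field(default=4, ge=1)
    roi_max_area: int = Field(default=2000, ge=1)
    roi_smooth_sigma_px: float = Field(default=1.0, ge=0)


class NeuroConfig(_Strict):
    """Neuronal ΔF/F parameters."""

    window: int = Field(default=200, ge=2)
    q: float = Field(default=0.08, gt=0, lt=1)
    baseline_mode: Literal["rolling", "global_min"] = "rolling"
    threshold_dff: float = 0.02
    min_sep_s: float = Field(default=1.0, ge=0)
    baseline_window_s: float = Field(default=10.0, gt=0)


class FlyConfig(_Strict):
    """Kenyon-cell odor-responder classification parameters."""

    n_pre: int = Field(default=17, ge=1)
    window: int = Field(default=10, ge=1)
    k: float = Field(default=2.0, gt=0)
    correction: Literal["subtract", "scaled"] = "subtract"


class SbrConfig(_Strict):
    use_max_signal: bool = False
    auto_top_frac: float = Field(default=0.01, gt=0, lt=1)
    auto_bottom_frac: float = Field(default=0.10, gt=0, lt=1)


class RunConfig(_Strict):
    """Top-level named parameter set for every pipeline."""

    calibration: CalibrationConfig = CalibrationConfig()
    motility: MotilityConfig = MotilityConfig()
    astro: AstroConfig = AstroConfig()
    neuro: NeuroConfig = NeuroConfig()
    fly: FlyConfig = FlyConfig()
    sbr: SbrConfig = SbrConfig()
    seed: Optional[int] = Field(default=None, ge=0)
    relabel_roi_gaps: bool = False


def load_config(path: str | Path | None) -> RunConfig:
    """Load a JSON run configuration, filling defaults; ``None`` → all defaults.

    Raises ``pydantic.ValidationError`` on unknown keys or out-of-range
    values, naming the offending key.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if text.strip() else {}
    return RunConfig.model_validate(data)
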